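import numpy as np
import pytest

from smilesforge.chem_core import Molecule
from smilesforge.fixtures import CorpusSpec, generate_corpus
from smilesforge.mutator import train_token_model
from smilesforge.objectives import EVS_NAME, ObjectiveVector
from smilesforge.pareto import Provenance, ScoredCandidate


def make_candidate(values, evs=0, smiles="C", fp_bits=None, width=32,
                   arrival=0, n_heavy=1):
    """Candidate with hand-set objectives/fingerprint, bypassing chemistry.

    `values` maps non-EVS objective names to floats; `fp_bits` is the
    set of on-bits of a synthetic fingerprint.
    """
    fp = np.zeros(width, dtype=np.uint8)
    if fp_bits:
        fp[list(fp_bits)] = 1
    mol = Molecule(smiles_input=smiles, smiles_canonical=smiles,
                   n_heavy=n_heavy, fingerprint=fp)
    vec = ObjectiveVector(values={EVS_NAME: float(evs), **values})
    return ScoredCandidate(mol, vec, Provenance(arrival_index=arrival))


def brute_force_dominance_counts(pool, names):
    """Independent O(n^2) strict-dominance scan (the test oracle)."""
    counts = []
    for x in pool:
        dom = 0
        for other in pool:
            if other is x:
                continue
            if all(other.objectives[n] > x.objectives[n] for n in names):
                dom += 1
        counts.append(dom)
    return counts


@pytest.fixture(scope="session")
def corpus():
    return generate_corpus(CorpusSpec(n_molecules=500, size_range=(8, 28),
                                      seed=20240901))


@pytest.fixture(scope="session")
def token_model(corpus):
    return train_token_model(corpus, order=2, mode="atom_token")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
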