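"""Synthetic inputs for desk-scale, fully offline runs.

Three generators stand in for inputs that cannot ship with the package:

* a fragment-grammar SMILES corpus (plays the role of a large training
  corpus for the substitution token model),
* a scored toy reference set (plays the role of a panel of known
  actives seeding the elite pool),
* deterministic surrogate docking scorers whose log-score grows with
  the log of the heavy-atom count with slope 0.35, emulating the
  empirical size dependence of real docking scores.

Every artifact is a pure function of its spec and seed.  The grammar
emits only valid SMILES by construction (the validator still checks
every output in the tests), and the two consensus surrogates carry
different structural bonuses so their rankings genuinely conflict and
the Pareto front is non-trivial.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_core import Molecule, canonicalize
from .errors import ScorerFailure
from .objectives import (
    CallableScorer,
    ObjectiveSetConfig,
    ObjectiveVector,
    ScorerContract,
    assemble_vector,
    surrogate_docking_score,
)
from .pareto import Provenance, ScoredCandidate

__all__ = [
    "CorpusSpec",
    "generate_corpus",
    "surrogate_objective_bundle",
    "make_reference_set",
    "write_reference_tsv",
]


@dataclass(frozen=True)
class CorpusSpec:
    """What the corpus generator should emit."""

    n_molecules: int = 500
    size_range: tuple[int, int] = (8, 28)   # heavy atoms
    seed: int = 0
    # relative weights of the grammar units, in the order of _UNITS
    weights: tuple[float, ...] = (5.0, 1.2, 1.0, 0.6, 1.0, 0.8, 1.2, 0.7, 0.9, 0.5)


# (smiles fragment, heavy atoms, needs-carbon-before, forbids-hetero-after)
# Fragments are chain units: concatenating them left to right always
# yields a valid SMILES as long as the adjacency rules below hold.
_UNITS: tuple[tuple[str, int, bool, bool], ...] = (
    ("C", 1, False, False),
    ("N", 1, True, False),
    ("O", 1, True, False),
    ("S", 1, True, False),
    ("C(=O)", 2, True, False),    # after carbon only: no anhydrides/peroxide paths
    ("C(=O)O", 3, True, True),    # ester/acid link: next unit must be carbon
    ("C(C)", 2, False, False),
    ("C1CCCCC1", 6, False, False),
    ("c1ccccc1", 6, False, False),
    ("c1ccncc1", 6, False, False),
)
_HETERO_START = {"N", "O", "S"}


def _grow_one(target: int, rng: np.random.Generator, weights: np.ndarray) -> str:
    """Assemble one molecule with exactly *target* heavy atoms."""
    parts = ["C"]
    remaining = target - 1
    carbon_last = True      # last emitted unit ends on / is carbon
    force_carbon = False    # next unit must start with aliphatic C
    while remaining > 0:
        usable = []
        for idx, (frag, size, needs_c, _) in enumerate(_UNITS):
            if size > remaining:
                continue
            if needs_c and not carbon_last:
                continue
            if force_carbon and (frag[0] not in "C" or frag.startswith("c")):
                continue
            usable.append(idx)
        probs = weights[usable] / weights[usable].sum()
        idx = int(rng.choice(usable, p=probs))
        frag, size, _, forces = _UNITS[idx]
        parts.append(frag)
        remaining -= size
        force_carbon = forces
        carbon_last = frag[0] not in _HETERO_START and not frag.endswith(")O")
        if frag == "C(=O)O":
            carbon_last = False
    return "".join(parts)


def generate_corpus(spec: CorpusSpec) -> list[str]:
    """n distinct valid SMILES from the closed fragment grammar.

    Collisions (the grammar re-emitting an already-seen structure) are
    resolved by regeneration, so the output is exactly ``n_molecules``
    distinct canonical structures, in a deterministic order for a fixed
    spec and seed.
    """
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.weights, dtype=float)
    lo, hi = spec.size_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad size range {spec.size_range}")
    seen: set[str] = set()
    out: list[str] = []
    guard = 0
    while len(out) < spec.n_molecules:
        guard += 1
        if guard > 200 * spec.n_molecules:  # pragma: no cover - safety valve
            raise RuntimeError("corpus generator stalled; widen the size range")
        target = int(rng.integers(lo, hi + 1))
        smiles = _grow_one(target, rng, weights)
        key = canonicalize(smiles)
        if key in seen:
            continue
        seen.add(key)
        out.append(smiles)
    return out


# ---------------------------------------------------------------------------
# surrogate scorers
# ---------------------------------------------------------------------------

def surrogate_objective_bundle(
    mode: str,
    seed: int,
    noise_sd: float = 0.10,
) -> dict[str, ScorerContract]:
    """One deterministic raw scorer per raw score the mode needs.

    The ChemPLP-like scorer rewards hetero-atom content, the GLIDE-like
    one rewards ring count; with independent noise streams the two are
    deliberately not rank-identical, so consensus fronts stay
    non-trivial.  Both emit raw scores in the minimize-raw convention
    (more negative is better), like the docking codes they emulate.
    """

    def _chemplp(smiles: str) -> float:
        mol = Molecule.from_smiles(smiles, do_standardize=False)
        return -surrogate_docking_score(
            mol, seed, slope=0.35, noise_sd=noise_sd,
            base=30.0, hetero_weight=0.5, ring_weight=0.0, label="chemplp",
        )

    def _glide(smiles: str) -> float:
        mol = Molecule.from_smiles(smiles, do_standardize=False)
        return -surrogate_docking_score(
            mol, seed, slope=0.35, noise_sd=noise_sd,
            base=3.0, hetero_weight=0.0, ring_weight=0.15, label="glide",
        )

    bundle: dict[str, ScorerContract] = {
        "chemplp": CallableScorer("chemplp_surrogate", _chemplp)
    }
    if mode == "consensus":
        bundle["glide"] = CallableScorer("glide_surrogate", _glide)
    elif mode != "plants_only":
        raise ValueError(f"unknown surrogate mode {mode!r}")
    return bundle


# ---------------------------------------------------------------------------
# reference set
# ---------------------------------------------------------------------------

def make_reference_set(
    n: int,
    config: ObjectiveSetConfig,
    seed: int,
    scorers: dict[str, ScorerContract] | None = None,
    size_range: tuple[int, int] = (12, 26),
) -> list[ScoredCandidate]:
    """n surrogate-scored molecules playing the role of known actives.

    Every member carries EVS = 1.  Scores are replayable from
    (SMILES, seed) because the surrogate scorers are deterministic.
    """
    if n < 1:
        raise ValueError("reference set needs n >= 1")
    scorers = scorers or surrogate_objective_bundle(config.mode, seed)
    corpus = generate_corpus(
        CorpusSpec(n_molecules=n, size_range=size_range, seed=seed + 1)
    )
    out: list[ScoredCandidate] = []
    for i, smiles in enumerate(corpus):
        mol = Molecule.from_smiles(smiles)
        raw = {name: sc.score_one(mol.smiles_canonical)
               for name, sc in scorers.items()}
        vec = assemble_vector(mol, raw, config, evs=1)
        out.append(ScoredCandidate(mol, vec, Provenance(arrival_index=i)))
    return out


def write_reference_tsv(
    references: Sequence[ScoredCandidate],
    names: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Engine reference dialect: 'smiles<TAB>obj1…objd' with a header.

    EVS is not a column; the engine's loader attaches EVS = 1 to every
    reference row.
    """
    non_evs = [n for n in names if n != "EVS"]
    with open(path, "w") as fh:
        fh.write("\t".join(["smiles", *non_evs]) + "\n")
        for cand in references:
            row = [cand.smiles] + [repr(cand.objectives[n]) for n in non_evs]
            fh.write("\t".join(row) + "\n")
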