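"""Build the synthetic inputs: a SMILES corpus and a scored reference set.

The corpus trains the substitution token model; the reference set plays
the role of a panel of known actives and seeds the elite pool with
EVS = 1.  Both are pure functions of their spec and seed.
"""

from smilesforge import CorpusSpec, generate_corpus, make_reference_set
from smilesforge.objectives import ObjectiveSetConfig

corpus = generate_corpus(CorpusSpec(n_molecules=10, size_range=(8, 20), seed=7))
print("corpus molecules:")
for smiles in corpus:
    print(" ", smiles)

config = ObjectiveSetConfig(mode="plants_only")
refs = make_reference_set(5, config, seed=7)
print("\nscored references (EVS=1, objectives oriented larger-is-fitter):")
for cand in refs:
    vals = ", ".join(f"{n}={cand.objectives[n]:.2f}"
                     for n in config.objectives)
    print(f"  {cand.smiles:<30s} {vals}")
print("\nplantsDS is the negated surrogate docking score; plantsLE and "
      "plantsPLE divide it by N_h and N_h^0.35 to remove the size bias.")
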