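"""Mutate a parent SMILES by sampling-with-substitutions.

A smoothed n-gram token model learns local SMILES syntax from the
corpus; mutation replaces 1-5 random token positions with tokens drawn
from the model and keeps the first proposal that parses to a valid
molecule (up to 1000 retries per position combination).
"""

import numpy as np

from smilesforge import CorpusSpec, generate_corpus, mutate_with_retries, train_token_model

corpus = generate_corpus(CorpusSpec(n_molecules=300, seed=11))
model = train_token_model(corpus, order=2, mode="atom_token")
rng = np.random.default_rng(11)

parent = corpus[0]
print(f"parent: {parent}")
for _ in range(5):
    out = mutate_with_retries(parent, model, rng)
    print(f"  child: {out.child_smiles}   "
          f"(substitutions={out.substitution_count}, "
          f"positions={out.positions}, attempts={out.attempts_used})")
print("\nEvery child is a valid molecule with the same token count as the "
      "parent; attempts counts how many samples the validity filter rejected.")
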