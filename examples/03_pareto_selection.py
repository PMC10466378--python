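"""Strict Pareto dominance, depth subsets and the EVS guarantee.

An item dominates another only when strictly better in EVERY objective.
The EVS objective (1 for validated actives, 0 for generated molecules)
therefore makes actives permanently non-dominated: nothing can beat
them on EVS.
"""

import numpy as np

from smilesforge import ElitePool, Molecule, merge_and_prune, pareto_front
from smilesforge.objectives import ObjectiveVector
from smilesforge.pareto import ScoredCandidate, dominance_counts

NAMES = ["EVS", "score_a", "score_b"]


def candidate(smiles, evs, a, b):
    mol = Molecule.from_smiles(smiles)
    vec = ObjectiveVector(values={"EVS": float(evs), "score_a": a, "score_b": b})
    return ScoredCandidate(mol, vec)


reference = candidate("CC(=O)Oc1ccccc1C(=O)O", evs=1, a=10.0, b=10.0)  # aspirin
strong = candidate("CCCCCCCCCC", evs=0, a=100.0, b=100.0)
weak = candidate("CCO", evs=0, a=5.0, b=5.0)

pool = [reference, strong, weak]
print("Dom values:", dict(zip([c.smiles for c in pool],
                              dominance_counts(pool, NAMES))))
front = pareto_front(pool, NAMES)
print("front:", [c.smiles for c in front])

elite = merge_and_prune(ElitePool([reference]), [strong, weak], NAMES)
print("elite after merge:", [c.smiles for c in elite])
print("\nThe generated molecule with scores (100, 100) joins the front but "
      "cannot evict the validated active: its EVS of 0 can never strictly "
      "beat 1.  The weak candidate is dominated by it and is pruned.")
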