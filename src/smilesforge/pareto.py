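"""Strict Pareto-dominance engine.

An item *a* dominates *b* when *a* is strictly better in EVERY
objective simultaneously — stricter than canonical Pareto dominance
(better-or-equal in all, strictly better in one), which is available
behind a switch.  The strict form is what makes the EVS guarantee work:
no generated item (EVS 0) can be strictly better than a reference
(EVS 1) in the EVS coordinate, so references are permanently
non-dominated.

Dom(x) is the number of pool members dominating x; the Pareto front is
the Dom = 0 subset, and the depth-k subset is Dom <= k.

Comparisons are exact floating-point ``>`` with no epsilon: scores come
from deterministic scorers, and an epsilon would silently change front
membership.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem_core import Molecule
from .errors import EmptyPool, MissingScore
from .objectives import EVS_NAME, ObjectiveVector

__all__ = [
    "Provenance",
    "ScoredCandidate",
    "ElitePool",
    "dominates",
    "dominance_count",
    "dominance_counts",
    "pareto_front",
    "depth_subset",
    "merge_and_prune",
    "write_pool_tsv",
    "read_pool_tsv",
]


@dataclass(frozen=True)
class Provenance:
    parent: str | None = None          # canonical SMILES of the parent, if any
    substitutions: int = 0
    arrival_index: int = -1


@dataclass(frozen=True)
class ScoredCandidate:
    molecule: Molecule
    objectives: ObjectiveVector
    provenance: Provenance = field(default_factory=Provenance)

    @property
    def smiles(self) -> str:
        return self.molecule.smiles_canonical

    @property
    def evs(self) -> int:
        return self.objectives.evs


# ---------------------------------------------------------------------------
# dominance primitives
# ---------------------------------------------------------------------------

def dominates(
    a: ObjectiveVector,
    b: ObjectiveVector,
    names: Sequence[str],
    *,
    strict_all: bool = True,
) -> bool:
    """True iff *a* dominates *b* on the listed objectives.

    Default is the strict form (``>`` in every objective).  With
    ``strict_all=False`` the canonical form is used (``>=`` in all and
    ``>`` in at least one).
    """
    av = a.as_tuple(names)
    bv = b.as_tuple(names)
    if strict_all:
        return all(x > y for x, y in zip(av, bv))
    return all(x >= y for x, y in zip(av, bv)) and any(
        x > y for x, y in zip(av, bv)
    )


def _matrix(pool: Sequence[ScoredCandidate], names: Sequence[str]) -> np.ndarray:
    return np.array([c.objectives.as_tuple(names) for c in pool], dtype=float)


def dominance_counts(
    pool: Sequence[ScoredCandidate],
    names: Sequence[str],
    *,
    strict_all: bool = True,
) -> np.ndarray:
    """Dom value for every pool member, via a vectorized pairwise scan."""
    pool = list(pool)
    if not pool:
        return np.zeros(0, dtype=int)
    v = _matrix(pool, names)
    # greater[j, i, k] : member j beats member i on objective k
    greater = v[:, None, :] > v[None, :, :]
    if strict_all:
        dom = greater.all(axis=2)
    else:
        geq = v[:, None, :] >= v[None, :, :]
        dom = geq.all(axis=2) & greater.any(axis=2)
    np.fill_diagonal(dom, False)
    return dom.sum(axis=0)


def dominance_count(
    x: ScoredCandidate,
    pool: Iterable[ScoredCandidate],
    names: Sequence[str],
    *,
    strict_all: bool = True,
) -> int:
    """Number of pool members (excluding x itself) that dominate x."""
    return sum(
        1
        for other in pool
        if other is not x and dominates(other.objectives, x.objectives, names,
                                        strict_all=strict_all)
    )


def pareto_front(
    pool: Sequence[ScoredCandidate],
    names: Sequence[str],
    *,
    strict_all: bool = True,
) -> list[ScoredCandidate]:
    """The non-dominated (Dom = 0) subset; never empty for a non-empty pool."""
    pool = list(pool)
    if not pool:
        raise EmptyPool("pareto_front of an empty pool")
    counts = dominance_counts(pool, names, strict_all=strict_all)
    return [c for c, d in zip(pool, counts) if d == 0]


def depth_subset(
    pool: Sequence[ScoredCandidate],
    names: Sequence[str],
    k: int,
    *,
    strict_all: bool = True,
) -> list[ScoredCandidate]:
    """Members with Dom <= k; k = 0 is the Pareto front, subsets nest in k."""
    if k < 0:
        raise ValueError("depth threshold k must be >= 0")
    pool = list(pool)
    if not pool:
        return []
    counts = dominance_counts(pool, names, strict_all=strict_all)
    return [c for c, d in zip(pool, counts) if d <= k]


# ---------------------------------------------------------------------------
# the elite pool
# ---------------------------------------------------------------------------

@dataclass
class ElitePool:
    """Current non-dominated parent pool.

    Under strict dominance every EVS=1 item ever inserted stays a member
    for the lifetime of the pool.
    """

    members: list[ScoredCandidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def smiles(self) -> list[str]:
        return [c.smiles for c in self.members]


def merge_and_prune(
    elite: ElitePool,
    new_items: Sequence[ScoredCandidate],
    names: Sequence[str],
    *,
    strict_all: bool = True,
) -> ElitePool:
    """Merge the elite pool with new candidates and keep the Pareto front.

    Strict dominance guarantees every EVS=1 member of the input
    survives: nothing can be strictly better in the EVS coordinate.
    """
    merged = list(elite.members) + list(new_items)
    if not merged:
        return ElitePool([])
    return ElitePool(pareto_front(merged, names, strict_all=strict_all))


# ---------------------------------------------------------------------------
# pool TSV round-trip
# ---------------------------------------------------------------------------

def write_pool_tsv(
    pool: Sequence[ScoredCandidate],
    names: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Write 'smiles<TAB>evs<TAB>obj1…objd<TAB>dom' with a header row."""
    non_evs = [n for n in names if n != EVS_NAME]
    counts = dominance_counts(list(pool), names)
    with open(path, "w") as handle:
        handle.write("\t".join(["smiles", "evs", *non_evs, "dom"]) + "\n")
        for cand, dom in zip(pool, counts):
            row = [cand.smiles, str(cand.evs)]
            row += [repr(cand.objectives[n]) for n in non_evs]
            row.append(str(int(dom)))
            handle.write("\t".join(row) + "\n")


def read_pool_tsv(path: str | os.PathLike) -> list[ScoredCandidate]:
    """Read a pool TSV written by :func:`write_pool_tsv` (lossless)."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["smiles", "evs"] or header[-1] != "dom":
            raise MissingScore(f"unrecognized pool header: {header}")
        obj_names = header[2:-1]
        out = []
        for i, line in enumerate(handle):
            parts = line.rstrip("\n").split("\t")
            smiles, evs = parts[0], int(parts[1])
            values = {EVS_NAME: float(evs)}
            values.update(
                {n: float(v) for n, v in zip(obj_names, parts[2:-1])}
            )
            out.append(
                ScoredCandidate(
                    molecule=Molecule.from_smiles(smiles, do_standardize=False),
                    objectives=ObjectiveVector(values=values),
                    provenance=Provenance(arrival_index=i),
                )
            )
    return out
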