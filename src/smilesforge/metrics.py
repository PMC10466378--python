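"""Library-quality analytics for generated focused libraries.

Internal diversity (mean Soergel distance over all unordered pairs on
radius-2 circular fingerprints), nearest-reference similarity and
Δ-score, exceedance time series against the reference set's best
values, dominance-depth reports, heavy-atom histograms and
synthetic-accessibility summaries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import sa_score, soergel_distance, tanimoto
from .errors import EmptyReference, MissingScore, TooFew
from .objectives import EVS_NAME
from .pareto import ScoredCandidate, dominance_counts

__all__ = [
    "internal_diversity",
    "nearest_reference",
    "delta_objective",
    "exceedance_series",
    "joint_exceedance_series",
    "depth_report",
    "heavy_atom_histogram",
    "sa_summary",
]


def internal_diversity(candidates: Sequence[ScoredCandidate]) -> float:
    """Mean Soergel (1 − Tanimoto) distance over all unordered distinct pairs.

    0 when every fingerprint is identical, 1 when all pairs are
    fingerprint-disjoint.  The pair mean equals the per-molecule mean of
    mean distances, so the two readings of "between each molecule and
    the others" coincide.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise TooFew("internal diversity needs at least 2 molecules")
    fps = np.array([c.molecule.fingerprint for c in candidates], dtype=bool)
    inter = (fps[:, None, :] & fps[None, :, :]).sum(axis=2)
    union = (fps[:, None, :] | fps[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        tan = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    n = len(candidates)
    iu = np.triu_indices(n, k=1)
    return float(np.mean(1.0 - tan[iu]))


def nearest_reference(
    candidate: ScoredCandidate,
    references: Sequence[ScoredCandidate],
) -> tuple[ScoredCandidate, float]:
    """Most similar reference by Tanimoto; ties broken by reference order."""
    references = list(references)
    if not references:
        raise EmptyReference("no references to compare against")
    best, best_tc = references[0], -1.0
    for ref in references:
        tc = tanimoto(candidate.molecule.fingerprint, ref.molecule.fingerprint)
        if tc > best_tc:
            best, best_tc = ref, tc
    return best, best_tc


def delta_objective(
    candidate: ScoredCandidate,
    references: Sequence[ScoredCandidate],
    name: str,
) -> float:
    """Objective difference generated − nearest reference neighbour.

    Positive values mean the generated molecule beats the most similar
    known active on that objective.
    """
    neighbour, _ = nearest_reference(candidate, references)
    return candidate.objectives[name] - neighbour.objectives[name]


def exceedance_series(
    candidates: Sequence[ScoredCandidate],
    name: str,
    ref_top: float,
) -> np.ndarray:
    """Cumulative count, in arrival order, of molecules strictly above *ref_top*."""
    values = np.array([c.objectives[name] for c in candidates], dtype=float)
    return np.cumsum(values > ref_top).astype(int)


def joint_exceedance_series(
    candidates: Sequence[ScoredCandidate],
    names: tuple[str, str],
    tops: tuple[float, float],
) -> np.ndarray:
    """Cumulative count of molecules strictly above BOTH thresholds."""
    a = np.array([c.objectives[names[0]] for c in candidates], dtype=float)
    b = np.array([c.objectives[names[1]] for c in candidates], dtype=float)
    return np.cumsum((a > tops[0]) & (b > tops[1])).astype(int)


def depth_report(
    pool: Sequence[ScoredCandidate],
    names: Sequence[str],
    thresholds: Sequence[int] = (0, 1, 3, 5),
) -> pd.DataFrame:
    """Per-depth subset sizes, diversity and SA summary.

    One row per Dom threshold k with the members at Dom <= k within the
    supplied pool (typically generated set ∪ references).  Generated
    (EVS 0) and reference (EVS 1) counts are reported separately;
    diversity and SA cover the whole subset.
    """
    pool = list(pool)
    counts = dominance_counts(pool, names)
    rows = []
    for k in thresholds:
        subset = [c for c, d in zip(pool, counts) if d <= k]
        n_ref = sum(1 for c in subset if c.evs == 1)
        sa_mean, sa_sd = sa_summary(subset) if subset else (float("nan"),) * 2
        rows.append(
            {
                "k": k,
                "n_total": len(subset),
                "n_generated": len(subset) - n_ref,
                "n_reference": n_ref,
                "internal_diversity": internal_diversity(subset)
                if len(subset) >= 2 else float("nan"),
                "sa_mean": sa_mean,
                "sa_sd": sa_sd,
            }
        )
    return pd.DataFrame(rows)


def heavy_atom_histogram(
    candidates: Sequence[ScoredCandidate],
    cutoff: int = 15,
) -> tuple[pd.Series, float]:
    """Counts per heavy-atom bin and the fraction strictly above *cutoff*."""
    sizes = pd.Series([c.molecule.n_heavy for c in candidates], dtype=int)
    hist = sizes.value_counts().sort_index()
    frac_above = float((sizes > cutoff).mean()) if len(sizes) else 0.0
    return hist, frac_above


def sa_summary(candidates: Sequence[ScoredCandidate]) -> tuple[float, float]:
    """Mean and population standard deviation of the SA score."""
    candidates = list(candidates)
    if not candidates:
        raise TooFew("SA summary of an empty set")
    scores = np.array(
        [sa_score(c.molecule.smiles_canonical) for c in candidates]
    )
    return float(scores.mean()), float(scores.std())
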