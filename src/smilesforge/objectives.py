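"""Objective-vector construction.

Docking back-ends report raw scores where *more negative is better*; the
optimizer works with sign-flipped scores so every objective is oriented
"larger is fitter".  Ligand efficiency (LE = DS / N_h) removes the raw
score's size bias in favour of fragments, while the pondered ligand
efficiency (PLE = DS / N_h^0.35) removes it without over-correcting: the
0.35 exponent is the empirical slope of log(DS) against log(N_h), so a
score that scales exactly as c·N_h^0.35 has PLE = c at every size.

The binary EVS (experimental validation status) objective — 1 for known
actives seeding the run, 0 for everything generated — makes the actives
permanently non-dominated under strict dominance and therefore
permanently eligible as parents.
"""

from __future__ import annotations

import hashlib
import math
import subprocess
from dataclasses import dataclass, field, replace
from statistics import NormalDist
from typing import Callable, Literal, Mapping, Sequence

from .chem_core import Molecule
from .errors import MissingScore, ScorerFailure, ZeroHeavyAtoms

__all__ = [
    "ObjectiveVector",
    "ObjectiveSetConfig",
    "ScorerContract",
    "CallableScorer",
    "ExternalScorer",
    "plants_ds",
    "glide_ds",
    "ligand_efficiency",
    "pondered_ligand_efficiency",
    "assemble_vector",
    "penalize",
    "surrogate_docking_score",
]

EVS_NAME = "EVS"
DEFAULT_PLE_EXPONENT = 0.35
DEFAULT_PENALTY = -1e9

PLANTS_ONLY_OBJECTIVES = (EVS_NAME, "plantsDS", "plantsLE", "plantsPLE")
CONSENSUS_OBJECTIVES = (EVS_NAME, "plantsDS", "plantsLE", "glideDS", "glideLE")


# ---------------------------------------------------------------------------
# score transforms
# ---------------------------------------------------------------------------

def plants_ds(raw_chemplp: float) -> float:
    """Negated ChemPLP score: fitter ligands score higher."""
    return -raw_chemplp


def glide_ds(raw_glide: float) -> float:
    """Negated GLIDE SP score: fitter ligands score higher."""
    return -raw_glide


def ligand_efficiency(ds: float, n_heavy: int) -> float:
    """ds / N_h — per-heavy-atom score."""
    if n_heavy < 1:
        raise ZeroHeavyAtoms(f"n_heavy must be >= 1, got {n_heavy}")
    return ds / n_heavy


def pondered_ligand_efficiency(
    ds: float, n_heavy: int, exponent: float = DEFAULT_PLE_EXPONENT
) -> float:
    """ds / N_h^exponent — size-debiased score.

    With the default exponent 0.35 (the empirical log–log slope of the
    docking score against heavy-atom count) a score of the form
    c·N_h^0.35 maps to c for every molecular size.
    """
    if n_heavy < 1:
        raise ZeroHeavyAtoms(f"n_heavy must be >= 1, got {n_heavy}")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    return ds / n_heavy**exponent


# ---------------------------------------------------------------------------
# objective vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveVector:
    """Named objectives, all oriented larger-is-fitter, plus the EVS flag."""

    values: Mapping[str, float]
    penalized: bool = False

    @property
    def evs(self) -> int:
        return int(self.values[EVS_NAME])

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise MissingScore(f"objective {name!r} absent") from None

    def as_tuple(self, names: Sequence[str]) -> tuple[float, ...]:
        return tuple(self[name] for name in names)


ObjectiveMode = Literal["plants_only", "consensus", "custom"]

# which raw score feeds each objective, and how
_RAW_OF_OBJECTIVE = {
    "plantsDS": "chemplp",
    "plantsLE": "chemplp",
    "plantsPLE": "chemplp",
    "glideDS": "glide",
    "glideLE": "glide",
}


@dataclass(frozen=True)
class ObjectiveSetConfig:
    """Which objectives a run optimizes and how raw scores map onto them."""

    mode: ObjectiveMode = "plants_only"
    objectives: tuple[str, ...] = ()
    ple_exponent: float = DEFAULT_PLE_EXPONENT
    penalty_value: float = DEFAULT_PENALTY
    # per-raw-score orientation: True (default) when more-negative raw is
    # better and the DS transform is a sign flip, as for both docking codes.
    minimize_raw: bool = True

    def __post_init__(self) -> None:
        if self.mode == "plants_only":
            object.__setattr__(self, "objectives", PLANTS_ONLY_OBJECTIVES)
        elif self.mode == "consensus":
            object.__setattr__(self, "objectives", CONSENSUS_OBJECTIVES)
        elif not self.objectives:
            raise ValueError("custom mode requires an explicit objective list")
        elif EVS_NAME not in self.objectives:
            object.__setattr__(
                self, "objectives", (EVS_NAME, *self.objectives)
            )

    @property
    def raw_score_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for obj in self.objectives:
            raw = _RAW_OF_OBJECTIVE.get(obj, obj if obj != EVS_NAME else None)
            if raw is not None and raw not in names:
                names.append(raw)
        return tuple(names)


def assemble_vector(
    mol: Molecule,
    raw_scores: Mapping[str, float],
    config: ObjectiveSetConfig,
    evs: int,
) -> ObjectiveVector:
    """Apply sign conventions and LE/PLE transforms; attach the EVS flag.

    Pure function of its arguments, so any archived vector can be
    replayed from the repository record.
    """
    if evs not in (0, 1):
        raise ValueError(f"evs must be 0 or 1, got {evs!r}")
    sign = -1.0 if config.minimize_raw else 1.0
    values: dict[str, float] = {EVS_NAME: float(evs)}
    for name in config.objectives:
        if name == EVS_NAME:
            continue
        raw_name = _RAW_OF_OBJECTIVE.get(name, name)
        if raw_name not in raw_scores:
            raise MissingScore(
                f"objective {name!r} needs raw score {raw_name!r}"
            )
        ds = sign * raw_scores[raw_name]
        if name.endswith("PLE"):
            values[name] = pondered_ligand_efficiency(
                ds, mol.n_heavy, config.ple_exponent
            )
        elif name.endswith("LE"):
            values[name] = ligand_efficiency(ds, mol.n_heavy)
        else:
            values[name] = ds
    return ObjectiveVector(values=values)


def penalize(config: ObjectiveSetConfig) -> ObjectiveVector:
    """All objectives at the sentinel, EVS 0, marked penalized.

    Penalized candidates are archived (they were visited) but can never
    reach the elite pool: any clean vector with positive scores and any
    reference dominates them.
    """
    values = {name: config.penalty_value for name in config.objectives}
    values[EVS_NAME] = 0.0
    return ObjectiveVector(values=values, penalized=True)


# ---------------------------------------------------------------------------
# scorer contract
# ---------------------------------------------------------------------------

class ScorerContract:
    """Anything that turns SMILES into one raw score per molecule.

    Deterministic for a fixed configuration; a failure on a molecule
    raises :class:`ScorerFailure` rather than returning a silent zero.
    """

    name: str = "scorer"

    def score_one(self, smiles: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def score_many(self, smiles: Sequence[str]) -> list[float]:
        return [self.score_one(s) for s in smiles]


class CallableScorer(ScorerContract):
    """Wrap a plain ``smiles -> float`` callable as a scorer."""

    def __init__(self, name: str, fn: Callable[[str], float]):
        self.name = name
        self._fn = fn

    def score_one(self, smiles: str) -> float:
        try:
            value = self._fn(smiles)
        except Exception as exc:
            raise ScorerFailure(f"{self.name} failed on {smiles!r}: {exc}") from exc
        if value is None or not math.isfinite(value):
            raise ScorerFailure(f"{self.name} returned {value!r} for {smiles!r}")
        return float(value)


class ExternalScorer(ScorerContract):
    """External executable scorer.

    Protocol: the command receives SMILES on standard input (one per
    line) and must emit ``SMILES<TAB>score`` lines on standard output.
    A non-zero exit or a malformed/missing line is a scorer error for
    the affected molecules.
    """

    def __init__(self, name: str, command: Sequence[str], timeout: float = 300.0):
        self.name = name
        self.command = list(command)
        self.timeout = timeout

    def score_one(self, smiles: str) -> float:
        return self.score_many([smiles])[0]

    def score_many(self, smiles: Sequence[str]) -> list[float]:
        try:
            proc = subprocess.run(
                self.command,
                input="".join(s + "\n" for s in smiles),
                capture_output=True,
                text=True,
                timeout=self.timeout,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise ScorerFailure(f"{self.name}: {exc}") from exc
        if proc.returncode != 0:
            raise ScorerFailure(
                f"{self.name} exited {proc.returncode}: {proc.stderr.strip()}"
            )
        table: dict[str, float] = {}
        for line in proc.stdout.splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ScorerFailure(f"{self.name}: malformed line {line!r}")
            try:
                table[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise ScorerFailure(f"{self.name}: bad score in {line!r}") from exc
        out = []
        for s in smiles:
            if s not in table:
                raise ScorerFailure(f"{self.name}: no score returned for {s!r}")
            out.append(table[s])
        return out


# ---------------------------------------------------------------------------
# deterministic surrogate scorer
# ---------------------------------------------------------------------------

def _hash_unit(*parts: object) -> float:
    """Deterministic uniform(0,1) from a string hash of the parts."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return (int.from_bytes(digest[:8], "big") + 0.5) / 2**64


def _hash_normal(*parts: object) -> float:
    return NormalDist().inv_cdf(_hash_unit(*parts))


def surrogate_docking_score(
    mol: Molecule,
    seed: int,
    slope: float = 0.35,
    noise_sd: float = 0.10,
    base: float = 30.0,
    hetero_weight: float = 0.0,
    ring_weight: float = 0.0,
    label: str = "surrogate",
) -> float:
    """Deterministic stand-in for a docking score (positive, larger fitter).

    log(score) = log(base) + slope·log(N_h) + hetero_weight·f_hetero
    + ring_weight·n_rings + ε, with ε a seeded hash perturbation of
    standard deviation *noise_sd*.  The same (canonical SMILES, seed)
    always yields the same score, and a log–log regression of score
    against heavy-atom count recovers *slope* when the structural terms
    and noise are small.
    """
    from rdkit import Chem

    rd = Chem.MolFromSmiles(mol.smiles_canonical)
    n_hetero = sum(1 for a in rd.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    n_rings = rd.GetRingInfo().NumRings()
    log_score = math.log(base) + slope * math.log(mol.n_heavy)
    log_score += hetero_weight * (n_hetero / mol.n_heavy)
    log_score += ring_weight * n_rings
    if noise_sd > 0:
        log_score += noise_sd * _hash_normal(label, seed, mol.smiles_canonical)
    return math.exp(log_score)
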