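"""The genetic-algorithm main loop.

The engine grows a focused library from a scored reference set: it
repeatedly draws a parent from the elite (non-dominated) pool, mutates
its SMILES with the sampling-with-substitutions operator, and pushes the
child through the processing pipeline — standardize, uniqueness check
against the append-only repository, reactive-group screen, scoring,
archive — before merging accepted candidates back into the elite pool.

Every reference molecule enters the run with EVS = 1 and therefore stays
in the elite pool forever (strict dominance cannot evict it); generated
molecules carry EVS = 0 and compete on the remaining objectives.

``run_no_ga`` is the ablation baseline: the identical pipeline, but
parents are drawn uniformly from everything accepted so far plus the
references, with no elite-pool restriction.

The module also implements the asynchronous master/worker file
protocol: workers write one-line score messages into a work directory;
the master periodically ingests them, owning uniqueness and the elite
pool.  The serial in-process mode used for testing produces the same
final state as a replay of the same arrival order.
"""

from __future__ import annotations

import os
import tempfile
import uuid
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .chem_core import Molecule, SmartsFilterSet, validate
from .errors import (
    EmptyPool,
    InvalidReference,
    InvalidStructure,
    MalformedMessage,
    MissingScore,
    ScorerFailure,
    StalledRun,
    UnscoredReference,
)
from .mutator import (
    DEFAULT_MAX_ATTEMPTS,
    DEFAULT_SUBSTITUTION_RANGE,
    TokenModel,
    mutate_with_retries,
)
from .objectives import (
    EVS_NAME,
    ObjectiveSetConfig,
    ObjectiveVector,
    ScorerContract,
    assemble_vector,
    penalize,
)
from .pareto import (
    ElitePool,
    Provenance,
    ScoredCandidate,
    merge_and_prune,
    pareto_front,
    write_pool_tsv,
)

__all__ = [
    "Repository",
    "RunConfig",
    "RunState",
    "initialize",
    "select_parent",
    "process_child",
    "run",
    "run_no_ga",
    "read_reference_tsv",
    "worker_emit",
    "master_collect",
]


# ---------------------------------------------------------------------------
# repository
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepositoryRecord:
    candidate: ScoredCandidate
    penalized: bool

    @property
    def smiles(self) -> str:
        return self.candidate.smiles


class Repository:
    """Append-only archive of every visited canonical SMILES.

    Keys are unique, arrival indices strictly increasing; the archive
    never shrinks during a run.  Penalized candidates are archived (they
    were visited, and the uniqueness check must see them) but are never
    eligible for the elite pool.
    """

    def __init__(self) -> None:
        self._records: dict[str, RepositoryRecord] = {}
        self._order: list[str] = []

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, canonical: str) -> RepositoryRecord:
        return self._records[canonical]

    @property
    def next_arrival_index(self) -> int:
        return len(self._order)

    def add(self, candidate: ScoredCandidate, penalized: bool = False) -> None:
        key = candidate.smiles
        if key in self._records:
            raise KeyError(f"{key!r} already archived")
        self._records[key] = RepositoryRecord(candidate, penalized)
        self._order.append(key)

    def records(self) -> list[RepositoryRecord]:
        return [self._records[k] for k in self._order]

    def accepted(self) -> list[ScoredCandidate]:
        """Clean, scored, generated molecules in arrival order (no references)."""
        return [
            r.candidate
            for r in self.records()
            if not r.penalized and r.candidate.evs == 0
        ]

    def references(self) -> list[ScoredCandidate]:
        return [r.candidate for r in self.records() if r.candidate.evs == 1]

    def to_tsv(self, names: Sequence[str], path: str | os.PathLike) -> None:
        non_evs = [n for n in names if n != EVS_NAME]
        with open(path, "w") as fh:
            header = ["smiles", "evs", *non_evs, "penalized", "parent",
                      "substitutions", "arrival_index"]
            fh.write("\t".join(header) + "\n")
            for rec in self.records():
                c = rec.candidate
                row = [c.smiles, str(c.evs)]
                row += [repr(c.objectives[n]) for n in non_evs]
                row += [
                    str(int(rec.penalized)),
                    c.provenance.parent or "-",
                    str(c.provenance.substitutions),
                    str(c.provenance.arrival_index),
                ]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    objective: ObjectiveSetConfig
    scorers: Mapping[str, ScorerContract]
    token_model: TokenModel
    target_unique: int = 100
    max_attempts: int = DEFAULT_MAX_ATTEMPTS
    substitution_range: tuple[int, int] = DEFAULT_SUBSTITUTION_RANGE
    seed: int = 0
    mode: Literal["ga", "no_ga"] = "ga"
    filters: SmartsFilterSet = field(default_factory=SmartsFilterSet)
    stall_limit: int = 20000  # consecutive non-accepting attempts before abort
    strict_all: bool = True

    def __post_init__(self) -> None:
        if self.target_unique < 1:
            raise ValueError("target_unique must be >= 1")


@dataclass
class RunState:
    config: RunConfig
    repository: Repository
    elite: ElitePool
    rng: np.random.Generator
    accepted: list[ScoredCandidate] = field(default_factory=list)
    counters: dict[str, int] = field(
        default_factory=lambda: {
            "accepted": 0, "duplicate": 0, "penalized": 0, "exhausted": 0,
        }
    )
    staged: list[ScoredCandidate] = field(default_factory=list)

    @property
    def objective_names(self) -> tuple[str, ...]:
        return self.config.objective.objectives


# ---------------------------------------------------------------------------
# reference loading and initialization
# ---------------------------------------------------------------------------

def read_reference_tsv(path: str | os.PathLike) -> list[tuple[str, dict[str, float]]]:
    """Read 'smiles<TAB>obj1…objd' rows under a header naming objectives."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "smiles":
            raise MalformedMessage(f"reference header must start with 'smiles': {header}")
        names = header[1:]
        rows = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise MalformedMessage(f"short reference row: {line!r}")
            rows.append((parts[0], {n: float(v) for n, v in zip(names, parts[1:])}))
    return rows


def initialize(
    reference: Sequence[tuple[str, dict[str, float]]],
    config: RunConfig,
) -> tuple[ElitePool, Repository]:
    """Build the starting elite pool and repository from scored references.

    Each reference gets EVS = 1 and enters both structures.  Under
    strict dominance EVS ties block reference-vs-reference domination,
    so the initial elite pool is the complete reference set.
    """
    if not reference:
        raise InvalidReference("reference set is empty")
    repo = Repository()
    members: list[ScoredCandidate] = []
    names = config.objective.objectives
    non_evs = [n for n in names if n != EVS_NAME]
    for smiles, values in reference:
        if not validate(smiles):
            raise InvalidReference(f"reference SMILES invalid: {smiles!r}")
        missing = [n for n in non_evs if n not in values]
        if missing:
            raise UnscoredReference(f"{smiles!r} missing objectives {missing}")
        mol = Molecule.from_smiles(smiles, filters=config.filters)
        vec = ObjectiveVector(
            values={EVS_NAME: 1.0, **{n: float(values[n]) for n in non_evs}}
        )
        cand = ScoredCandidate(
            mol, vec, Provenance(arrival_index=repo.next_arrival_index)
        )
        repo.add(cand)
        members.append(cand)
    elite = ElitePool(pareto_front(members, names, strict_all=config.strict_all))
    return elite, repo


def select_parent(elite: ElitePool, rng: np.random.Generator) -> ScoredCandidate:
    """Uniform random member of the elite pool."""
    if len(elite) == 0:
        raise EmptyPool("cannot select a parent from an empty pool")
    return elite.members[int(rng.integers(len(elite)))]


# ---------------------------------------------------------------------------
# child processing pipeline
# ---------------------------------------------------------------------------

def _score_raw(state: RunState, canonical: str) -> dict[str, float]:
    return {
        name: scorer.score_one(canonical)
        for name, scorer in state.config.scorers.items()
    }


def process_child(
    child_smiles: str,
    state: RunState,
    *,
    provenance: Provenance | None = None,
    precomputed_raw: Mapping[str, float] | None = None,
) -> Literal["accepted", "duplicate", "penalized"]:
    """Standardize, uniqueness-check, screen, score and archive one child.

    Returns the outcome class.  Accepted candidates are also staged for
    the next elite-pool merge.
    """
    config = state.config
    try:
        mol = Molecule.from_smiles(child_smiles, filters=config.filters)
    except InvalidStructure:
        # caller promised a valid SMILES; treat a late parse failure as
        # a scorer-style casualty rather than crashing the run
        state.counters["penalized"] += 1
        return "penalized"
    key = mol.smiles_canonical
    if key in state.repository:
        state.counters["duplicate"] += 1
        return "duplicate"
    prov = provenance or Provenance()
    prov = Provenance(prov.parent, prov.substitutions,
                      state.repository.next_arrival_index)
    if not mol.is_clean:
        cand = ScoredCandidate(mol, penalize(config.objective), prov)
        state.repository.add(cand, penalized=True)
        state.counters["penalized"] += 1
        return "penalized"
    try:
        raw = dict(precomputed_raw) if precomputed_raw is not None \
            else _score_raw(state, key)
        vec = assemble_vector(mol, raw, config.objective, evs=0)
    except (ScorerFailure, MissingScore):
        cand = ScoredCandidate(mol, penalize(config.objective), prov)
        state.repository.add(cand, penalized=True)
        state.counters["penalized"] += 1
        return "penalized"
    cand = ScoredCandidate(mol, vec, prov)
    state.repository.add(cand)
    state.accepted.append(cand)
    state.staged.append(cand)
    state.counters["accepted"] += 1
    return "accepted"


def _flush_staged(state: RunState) -> None:
    if state.staged:
        state.elite = merge_and_prune(
            state.elite, state.staged, state.objective_names,
            strict_all=state.config.strict_all,
        )
        state.staged.clear()


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _run_loop(
    reference: Sequence[tuple[str, dict[str, float]]],
    config: RunConfig,
    *,
    elite_selection: bool,
) -> RunState:
    elite, repo = initialize(reference, config)
    rng = np.random.default_rng(config.seed)
    state = RunState(config=config, repository=repo, elite=elite, rng=rng)
    references = repo.references()
    since_last_accept = 0
    while state.counters["accepted"] < config.target_unique:
        if elite_selection:
            parent = select_parent(state.elite, rng)
        else:
            pool = references + state.accepted
            parent = pool[int(rng.integers(len(pool)))]
        outcome = mutate_with_retries(
            parent.smiles, config.token_model, rng,
            max_attempts=config.max_attempts,
            count_range=config.substitution_range,
        )
        if outcome.exhausted:
            # one redraw of the position combination, then a fresh parent
            outcome = mutate_with_retries(
                parent.smiles, config.token_model, rng,
                max_attempts=config.max_attempts,
                count_range=config.substitution_range,
            )
        if outcome.exhausted:
            state.counters["exhausted"] += 1
            since_last_accept += 1
        else:
            prov = Provenance(parent=parent.smiles,
                              substitutions=outcome.substitution_count)
            status = process_child(outcome.child_smiles, state, provenance=prov)
            if status == "accepted":
                _flush_staged(state)
                since_last_accept = 0
            else:
                since_last_accept += 1
        if since_last_accept >= config.stall_limit:
            raise StalledRun(
                f"no acceptance in {since_last_accept} consecutive attempts"
            )
    return state


def run(reference, config: RunConfig) -> RunState:
    """GA mode: parents come from the elite (non-dominated) pool."""
    return _run_loop(reference, config, elite_selection=True)


def run_no_ga(reference, config: RunConfig) -> RunState:
    """Ablation mode: parents drawn uniformly from all accepted ∪ references."""
    return _run_loop(reference, config, elite_selection=False)


def write_run_outputs(state: RunState, workdir: str | os.PathLike) -> None:
    """best_pool.tsv (elite) and repository.tsv (archive) under *workdir*."""
    os.makedirs(workdir, exist_ok=True)
    names = state.objective_names
    write_pool_tsv(state.elite.members, names,
                   os.path.join(workdir, "best_pool.tsv"))
    state.repository.to_tsv(names, os.path.join(workdir, "repository.tsv"))


# ---------------------------------------------------------------------------
# asynchronous master/worker file protocol
# ---------------------------------------------------------------------------

_MSG_DIR = "msgs"
_QUARANTINE_DIR = "quarantine"


def worker_emit(
    smiles: str,
    values: Sequence[float],
    workdir: str | os.PathLike,
) -> str:
    """Atomically write a one-line 'smiles<TAB>scores…' message file.

    Write-then-rename guarantees the master never reads a half-written
    message.  Returns the message path.
    """
    msg_dir = os.path.join(workdir, _MSG_DIR)
    os.makedirs(msg_dir, exist_ok=True)
    line = "\t".join([smiles, *[repr(float(v)) for v in values]]) + "\n"
    fd, tmp = tempfile.mkstemp(dir=msg_dir, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(line)
    final = os.path.join(msg_dir, f"{uuid.uuid4().hex}.msg")
    os.replace(tmp, final)
    return final


def master_collect(
    workdir: str | os.PathLike,
    n_scores: int,
) -> list[tuple[str, list[float]]]:
    """Ingest pending worker messages; quarantine malformed ones.

    Processed message files are deleted; malformed files are moved to
    ``msgs/quarantine/`` and never crash the master.  Messages are
    returned in filename order, which replay uses as the arrival order.
    """
    msg_dir = os.path.join(workdir, _MSG_DIR)
    if not os.path.isdir(msg_dir):
        return []
    quarantine = os.path.join(msg_dir, _QUARANTINE_DIR)
    out: list[tuple[str, list[float]]] = []
    for name in sorted(os.listdir(msg_dir)):
        path = os.path.join(msg_dir, name)
        if not name.endswith(".msg") or not os.path.isfile(path):
            continue
        try:
            with open(path) as fh:
                parts = fh.readline().rstrip("\n").split("\t")
            if len(parts) != 1 + n_scores or not validate(parts[0]):
                raise MalformedMessage(name)
            record = (parts[0], [float(v) for v in parts[1:]])
        except (MalformedMessage, ValueError, OSError):
            os.makedirs(quarantine, exist_ok=True)
            os.replace(path, os.path.join(quarantine, name))
            continue
        out.append(record)
        os.remove(path)
    return out


def master_ingest(
    state: RunState,
    messages: Sequence[tuple[str, list[float]]],
) -> dict[str, int]:
    """Run collected worker records through the uniqueness/archive pipeline.

    Workers score; the master owns uniqueness, the repository and the
    elite pool, so racing workers that hit the same SMILES resolve to a
    single archived record.
    """
    raw_names = list(state.config.scorers.keys())
    tally = {"accepted": 0, "duplicate": 0, "penalized": 0}
    for smiles, values in messages:
        status = process_child(
            smiles, state,
            precomputed_raw=dict(zip(raw_names, values)),
        )
        tally[status] += 1
    _flush_staged(state)
    return tally
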