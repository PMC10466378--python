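"""Sampling-with-substitutions mutation operator.

The mutation rewrites a parent SMILES by replacing a randomly chosen
number of token positions (1–5 by default) with tokens drawn from a
conditional probability model of SMILES syntax.  The shipped model is a
smoothed n-gram over a training corpus — a deliberately simple,
fully-deterministic stand-in for a trained neural generator; any
external generator honouring the plug-in protocol can replace it
without touching the engine.

Most random rewrites of a SMILES string are syntactically or chemically
invalid, so the operator retries the token sampling (positions held
fixed) up to ``max_attempts`` times and reports exhaustion as a value,
letting the caller redraw positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem_core import TokenMode, tokenize, validate
from .errors import (
    EmptyCorpus,
    TokenizationError,
    TooManySubstitutions,
)

__all__ = [
    "TokenModel",
    "MutationOutcome",
    "train_token_model",
    "sample_substitution_count",
    "sample_positions",
    "propose_child",
    "mutate_with_retries",
    "save_token_model",
    "load_token_model",
]

DEFAULT_ORDER = 2
DEFAULT_MAX_ATTEMPTS = 1000
DEFAULT_SUBSTITUTION_RANGE = (1, 5)
_SMOOTHING = 1.0  # add-one


@dataclass(frozen=True)
class TokenModel:
    """Smoothed conditional distribution over substitution tokens.

    ``conditional`` maps a left-context tuple (up to ``order`` tokens)
    to raw counts; sampling applies add-one smoothing over the full
    alphabet, so every token has non-zero probability in every context
    and unseen contexts fall back to the unconditional frequencies.
    """

    alphabet: tuple[str, ...]
    order: int
    mode: TokenMode
    conditional: Mapping[tuple[str, ...], Mapping[str, int]]
    fallback: Mapping[str, int]

    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.alphabet)}
        )

    def _probs(self, counts: Mapping[str, int]) -> np.ndarray:
        vec = np.full(len(self.alphabet), _SMOOTHING)
        for tok, c in counts.items():
            vec[self._index[tok]] += c
        return vec / vec.sum()

    def distribution(self, context: Sequence[str]) -> np.ndarray:
        """Smoothed P(token | context); sums to 1 over the alphabet."""
        ctx = tuple(context[-self.order:]) if self.order else ()
        counts = self.conditional.get(ctx)
        if counts is None:
            counts = self.fallback
        return self._probs(counts)

    def sample(self, context: Sequence[str], rng: np.random.Generator) -> str:
        return self.alphabet[rng.choice(len(self.alphabet),
                                        p=self.distribution(context))]


def train_token_model(
    corpus: Sequence[str],
    order: int = DEFAULT_ORDER,
    mode: TokenMode = "atom_token",
) -> TokenModel:
    """Fit the n-gram substitution model on a corpus of valid SMILES."""
    if not corpus:
        raise EmptyCorpus("token model needs a non-empty corpus")
    alphabet: set[str] = set()
    conditional: dict[tuple[str, ...], dict[str, int]] = {}
    fallback: dict[str, int] = {}
    for smiles in corpus:
        tokens = tokenize(smiles, mode)
        alphabet.update(tokens)
        for i, tok in enumerate(tokens):
            fallback[tok] = fallback.get(tok, 0) + 1
            ctx = tuple(tokens[max(0, i - order):i]) if order else ()
            bucket = conditional.setdefault(ctx, {})
            bucket[tok] = bucket.get(tok, 0) + 1
    return TokenModel(
        alphabet=tuple(sorted(alphabet)),
        order=order,
        mode=mode,
        conditional=conditional,
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def sample_substitution_count(
    rng: np.random.Generator,
    count_range: tuple[int, int] = DEFAULT_SUBSTITUTION_RANGE,
) -> int:
    """Uniform draw of the number of substitutions (default 1–5)."""
    lo, hi = count_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad substitution range {count_range}")
    return int(rng.integers(lo, hi + 1))


def sample_positions(
    n_tokens: int, s: int, rng: np.random.Generator
) -> list[int]:
    """s distinct token positions, uniform without replacement."""
    if s > n_tokens:
        raise TooManySubstitutions(
            f"{s} substitutions requested for {n_tokens} tokens"
        )
    return sorted(int(i) for i in rng.choice(n_tokens, size=s, replace=False))


def propose_child(
    parent: str,
    model: TokenModel,
    positions: Sequence[int],
    rng: np.random.Generator,
) -> str:
    """Rewrite the parent at the given positions, left to right.

    The context for each sampled token includes tokens already
    substituted earlier in the scan.  The proposal may be invalid or
    equal to the parent; the caller filters.
    """
    try:
        tokens = tokenize(parent, model.mode)
    except Exception as exc:
        raise TokenizationError(f"cannot tokenize {parent!r}: {exc}") from exc
    if any(not 0 <= p < len(tokens) for p in positions):
        raise TokenizationError(f"positions {positions} out of range")
    for pos in sorted(positions):
        tokens[pos] = model.sample(tokens[:pos], rng)
    return "".join(tokens)


@dataclass(frozen=True)
class MutationOutcome:
    """Result of one bounded mutation session on a single parent."""

    child_smiles: str | None
    attempts_used: int
    substitution_count: int
    positions: tuple[int, ...]

    @property
    def exhausted(self) -> bool:
        return self.child_smiles is None


def mutate_with_retries(
    parent: str,
    model: TokenModel,
    rng: np.random.Generator,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    count_range: tuple[int, int] = DEFAULT_SUBSTITUTION_RANGE,
) -> MutationOutcome:
    """Draw a substitution count and positions once, then retry sampling.

    Returns the first proposal that validates.  After ``max_attempts``
    invalid proposals the outcome carries ``child_smiles=None``,
    signalling the caller to select a new combination of positions.
    """
    tokens = tokenize(parent, model.mode)
    s = sample_substitution_count(rng, count_range)
    s = min(s, len(tokens))
    positions = tuple(sample_positions(len(tokens), s, rng))
    for attempt in range(1, max_attempts + 1):
        child = propose_child(parent, model, positions, rng)
        if validate(child):
            return MutationOutcome(child, attempt, s, positions)
    return MutationOutcome(None, max_attempts, s, positions)


# ---------------------------------------------------------------------------
# plain-text model serialization
# ---------------------------------------------------------------------------

_FORMAT_HEADER = "smilesforge-token-model\t1"


def save_token_model(model: TokenModel, path: str | os.PathLike) -> None:
    """Versioned plain-text dump: alphabet, then 'context TAB token TAB count'."""
    with open(path, "w") as fh:
        fh.write(_FORMAT_HEADER + "\n")
        fh.write(f"order\t{model.order}\n")
        fh.write(f"mode\t{model.mode}\n")
        fh.write("alphabet\t" + " ".join(model.alphabet) + "\n")
        for tok, c in sorted(model.fallback.items()):
            fh.write(f"F\t{tok}\t{c}\n")
        for ctx, bucket in sorted(model.conditional.items()):
            for tok, c in sorted(bucket.items()):
                fh.write(f"C\t{' '.join(ctx)}\t{tok}\t{c}\n")


def load_token_model(path: str | os.PathLike) -> TokenModel:
    with open(path) as fh:
        if fh.readline().rstrip("\n") != _FORMAT_HEADER:
            raise ValueError(f"{path}: not a token-model file")
        order = int(fh.readline().split("\t")[1])
        mode = fh.readline().split("\t")[1].strip()
        alphabet = tuple(fh.readline().rstrip("\n").split("\t")[1].split(" "))
        fallback: dict[str, int] = {}
        conditional: dict[tuple[str, ...], dict[str, int]] = {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "F":
                fallback[parts[1]] = int(parts[2])
            else:
                ctx = tuple(parts[1].split(" ")) if parts[1] else ()
                conditional.setdefault(ctx, {})[parts[2]] = int(parts[3])
    return TokenModel(alphabet=alphabet, order=order, mode=mode,  # type: ignore[arg-type]
                      conditional=conditional, fallback=fallback)
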