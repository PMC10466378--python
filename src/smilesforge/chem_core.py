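"""SMILES handling primitives.

Validation, standardization, canonicalization, tokenization, heavy-atom
counts, radius-2 circular (Morgan) fingerprints, Tanimoto/Soergel
similarity, SMARTS reactive-group screening, and the Ertl–Schuffenhauer
synthetic-accessibility score.  Everything downstream (objectives, the
mutation operator, the engine, the analytics) builds on this module.
"""

from __future__ import annotations

import os
import re
import sys
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import RDConfig, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import (
    InvalidStructure,
    UnterminatedBracket,
    WidthMismatch,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "SmartsFilterSet",
    "DEFAULT_REACTIVE_FILTERS",
    "validate",
    "standardize",
    "canonicalize",
    "heavy_atom_count",
    "fingerprint",
    "tanimoto",
    "soergel_distance",
    "reactive_screen",
    "sa_score",
    "tokenize",
    "read_smiles_file",
]

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_WIDTH = 2048


# ---------------------------------------------------------------------------
# parsing / normalisation
# ---------------------------------------------------------------------------

def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def validate(smiles: str) -> bool:
    """True iff *smiles* parses to a valence-legal structure.

    Never raises: malformed text (unmatched ring closures, illegal
    valences, stray characters) simply returns False.
    """
    return _mol_from_smiles(smiles) is not None


def canonicalize(smiles: str) -> str:
    """Deterministic canonical spelling; equal structures map to equal text."""
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise InvalidStructure(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def standardize(smiles: str) -> str:
    """Largest organic fragment, charges neutralized, canonical spelling.

    Idempotent: applied to its own output it is the identity.  A fixed
    point is reached by iterating the fragment/uncharge step (uncharging
    can in principle change which fragment is largest).
    """
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise InvalidStructure(f"unparseable SMILES: {smiles!r}")
    previous = None
    current = Chem.MolToSmiles(mol)
    for _ in range(5):
        if current == previous:
            break
        previous = current
        mol = _uncharger.uncharge(_largest_fragment.choose(mol))
        current = Chem.MolToSmiles(mol)
        mol = Chem.MolFromSmiles(current)
        if mol is None:  # pragma: no cover - standardization kept it parseable
            raise InvalidStructure(f"standardization broke {smiles!r}")
    return current


def heavy_atom_count(smiles_or_mol: "str | Chem.Mol | Molecule") -> int:
    """Number of non-hydrogen atoms."""
    if isinstance(smiles_or_mol, Molecule):
        return smiles_or_mol.n_heavy
    if isinstance(smiles_or_mol, Chem.Mol):
        return smiles_or_mol.GetNumHeavyAtoms()
    mol = _mol_from_smiles(smiles_or_mol)
    if mol is None:
        raise InvalidStructure(f"unparseable SMILES: {smiles_or_mol!r}")
    return mol.GetNumHeavyAtoms()


# ---------------------------------------------------------------------------
# fingerprints and similarity
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _morgan_generator(radius: int, width: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)


def fingerprint(
    smiles_or_mol: "str | Chem.Mol",
    radius: int = DEFAULT_FP_RADIUS,
    width: int = DEFAULT_FP_WIDTH,
) -> np.ndarray:
    """Binary circular fingerprint as a uint8 vector of length *width*."""
    if isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = _mol_from_smiles(smiles_or_mol)
        if mol is None:
            raise InvalidStructure(f"unparseable SMILES: {smiles_or_mol!r}")
    bv = _morgan_generator(radius, width).GetFingerprint(mol)
    arr = np.zeros(width, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∧ b| / |a ∨ b| on binary vectors.

    The degenerate all-zero/all-zero pair is defined as 1.0 (identical
    emptiness) and a warning is emitted.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise WidthMismatch(f"fingerprint widths differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 1.0",
                      stacklevel=2)
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def soergel_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − Tanimoto; a metric on binary vectors."""
    return 1.0 - tanimoto(a, b)


# ---------------------------------------------------------------------------
# reactive-group screen
# ---------------------------------------------------------------------------

# Structural alerts for reactive or chemically unstable groups.  The exact
# list is configurable; these defaults cover the classic electrophilic /
# explosive functionalities a medicinal chemist would strip from a de novo
# library before synthesis triage.
DEFAULT_REACTIVE_FILTERS: tuple[tuple[str, str], ...] = (
    ("acyl_halide", "[CX3](=O)[Cl,Br,I]"),
    ("isocyanate", "[NX2]=C=[OX1]"),
    ("nitroalkene", "[CX3]=[CX3][N+](=O)[O-]"),
    ("peroxide", "[OX2][OX2]"),
    ("azide", "[NX2]=[N+]=[N-]"),
    ("anhydride", "[CX3](=O)[OX2][CX3](=O)"),
    ("aldehyde_enol", "[OX2H][CX3]=[CX3][CX3H1]=O"),
)


@dataclass(frozen=True)
class SmartsFilterSet:
    """Ordered list of labelled SMARTS patterns; empty list disables the screen."""

    patterns: tuple[tuple[str, str], ...] = DEFAULT_REACTIVE_FILTERS

    def __post_init__(self) -> None:
        compiled = []
        for label, smarts in self.patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"SMARTS for {label!r} does not compile: {smarts!r}")
            compiled.append((label, query))
        object.__setattr__(self, "_compiled", tuple(compiled))

    @classmethod
    def empty(cls) -> "SmartsFilterSet":
        return cls(patterns=())

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "SmartsFilterSet":
        """Load 'label<TAB>SMARTS' lines; blank lines and '#' comments ignored."""
        patterns = []
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, smarts = line.split("\t", 1)
                patterns.append((label, smarts))
        return cls(patterns=tuple(patterns))

    def screen(self, mol: Chem.Mol) -> tuple[bool, list[str]]:
        hits = [label for label, query in self._compiled
                if mol.HasSubstructMatch(query)]
        return (not hits, hits)


def reactive_screen(
    smiles_or_mol: "str | Chem.Mol | Molecule",
    filters: SmartsFilterSet | None = None,
) -> tuple[bool, list[str]]:
    """(passes, hit labels) for the reactive/unstable-group substructure screen."""
    filters = filters if filters is not None else SmartsFilterSet()
    if isinstance(smiles_or_mol, Molecule):
        mol = _mol_from_smiles(smiles_or_mol.smiles_canonical)
    elif isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = _mol_from_smiles(smiles_or_mol)
    if mol is None:
        raise InvalidStructure("reactive_screen needs a valid structure")
    return filters.screen(mol)


# ---------------------------------------------------------------------------
# synthetic accessibility
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _sascorer():
    # Ertl–Schuffenhauer reference implementation shipped with RDKit's
    # contrib tree; imported lazily so the package imports without it.
    contrib = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if contrib not in sys.path:
        sys.path.append(contrib)
    import sascorer  # type: ignore

    return sascorer


def sa_score(smiles_or_mol: "str | Chem.Mol | Molecule") -> float:
    """Synthetic-accessibility score, clamped to [1, 10] (1 easy, 10 hard)."""
    if isinstance(smiles_or_mol, Molecule):
        mol = _mol_from_smiles(smiles_or_mol.smiles_canonical)
    elif isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = _mol_from_smiles(smiles_or_mol)
    if mol is None:
        raise InvalidStructure("sa_score needs a valid structure")
    return float(min(10.0, max(1.0, _sascorer().calculateScore(mol))))


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

# atom_token mode: bracket atoms, two-letter organic-subset elements, the
# %nn two-digit ring-closure form and every remaining single character.
_ATOM_TOKEN_RE = re.compile(r"\[[^\]]*\]|Cl|Br|%\d{2}|.")

TokenMode = Literal["character", "atom_token"]


def tokenize(smiles: str, mode: TokenMode = "atom_token") -> list[str]:
    """Split SMILES into tokens; concatenating them reproduces the input.

    ``character`` mode is a plain character split.  ``atom_token`` mode
    keeps two-letter elements (Cl, Br), bracket atoms ``[...]`` and
    two-digit ring closures ``%nn`` as single tokens.
    """
    if mode == "character":
        return list(smiles)
    if mode != "atom_token":
        raise ValueError(f"unknown tokenization mode: {mode!r}")
    if "[" in smiles:
        depth = 0
        for ch in smiles:
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
            if depth not in (0, 1):
                raise UnterminatedBracket(f"malformed brackets in {smiles!r}")
        if depth != 0:
            raise UnterminatedBracket(f"unterminated bracket in {smiles!r}")
    return _ATOM_TOKEN_RE.findall(smiles)


# ---------------------------------------------------------------------------
# the Molecule record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Molecule:
    """A standardized molecule: canonical SMILES plus cached descriptors.

    ``is_clean`` records the outcome of the reactive-group screen with
    whichever filter set built the record.
    """

    smiles_input: str
    smiles_canonical: str
    n_heavy: int
    fingerprint: np.ndarray = field(repr=False, compare=False)
    is_clean: bool = True

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        *,
        do_standardize: bool = True,
        filters: SmartsFilterSet | None = None,
        fp_radius: int = DEFAULT_FP_RADIUS,
        fp_width: int = DEFAULT_FP_WIDTH,
    ) -> "Molecule":
        canonical = standardize(smiles) if do_standardize else canonicalize(smiles)
        mol = _mol_from_smiles(canonical)
        n_heavy = mol.GetNumHeavyAtoms()
        if n_heavy < 1:
            raise InvalidStructure(f"no heavy atoms in {smiles!r}")
        passes, _ = reactive_screen(mol, filters)
        return cls(
            smiles_input=smiles,
            smiles_canonical=canonical,
            n_heavy=n_heavy,
            fingerprint=fingerprint(mol, fp_radius, fp_width),
            is_clean=passes,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | os.PathLike) -> list[str]:
    """Read a .smi-dialect file: one SMILES per line, optional tab-separated
    identifier; blank lines and '#' comments ignored."""
    out: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t", 1)[0].split()[0])
    return out


def write_smiles_file(smiles: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for s in smiles:
            handle.write(s + "\n")
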