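"""Exception types shared across the package."""


class SmilesForgeError(Exception):
    """Base class for all package errors."""


class InvalidStructure(SmilesForgeError):
    """SMILES text does not parse to a chemically sane structure."""


class WidthMismatch(SmilesForgeError):
    """Fingerprints of unequal width were compared."""


class UnterminatedBracket(SmilesForgeError):
    """Atom-token SMILES tokenization hit a '[' without a matching ']'."""


class ZeroHeavyAtoms(SmilesForgeError):
    """Ligand-efficiency transform received a heavy-atom count < 1."""


class MissingScore(SmilesForgeError):
    """An objective vector lacks a required objective name."""


class ScorerFailure(SmilesForgeError):
    """An external or surrogate scorer failed on a molecule."""


class EmptyPool(SmilesForgeError):
    """A non-empty candidate pool was required."""


class EmptyCorpus(SmilesForgeError):
    """Token-model training requires a non-empty corpus."""


class TooManySubstitutions(SmilesForgeError):
    """More substitution positions requested than tokens available."""


class TokenizationError(SmilesForgeError):
    """Parent SMILES could not be tokenized for mutation."""


class UnscoredReference(SmilesForgeError):
    """A reference molecule is missing one of the configured objectives."""


class InvalidReference(SmilesForgeError):
    """A reference SMILES failed validation or standardization."""


class StalledRun(SmilesForgeError):
    """The engine made no acceptance within the configured attempt window."""


class MalformedMessage(SmilesForgeError):
    """A worker message file could not be parsed."""


class TooFew(SmilesForgeError):
    """A set-level metric needs more members than were supplied."""


class EmptyReference(SmilesForgeError):
    """Nearest-reference lookup against an empty reference set."""
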