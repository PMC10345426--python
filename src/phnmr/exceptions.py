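"""Exception hierarchy for phnmr."""


class PhnmrError(Exception):
    """Base class for all phnmr errors."""


class ParseError(PhnmrError):
    """A file could not be parsed; the message names the offending record."""


class RosterError(PhnmrError):
    """Models of an ensemble do not share one (chain, residue, atom) roster."""


class SelectionError(PhnmrError):
    """An atom/residue selection is empty or names unknown atoms."""


class CoverageError(PhnmrError):
    """A residue correspondence references residues/atoms absent from a structure."""


class DimensionError(PhnmrError):
    """Coordinate matrices have incompatible shapes."""


class ConditioningError(PhnmrError):
    """Point geometry is too degenerate for a stable superposition."""


class AlphabetError(PhnmrError):
    """A sequence contains characters outside the amino-acid alphabet."""


class UndefinedIdentityError(PhnmrError):
    """Percent identity requested over an empty region."""


class SchemeError(PhnmrError):
    """An NOE intensity class is absent from the binning scheme."""


class UndefinedRatioError(PhnmrError):
    """Heteronuclear NOE is undefined because the reference intensity is <= 0."""


class ParameterError(PhnmrError):
    """Non-physical model parameters (e.g. Ka <= 0)."""


class PrecisionUndefinedError(PhnmrError):
    """Ensemble precision requested for a single-model ensemble."""
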