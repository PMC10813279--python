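"""Exception hierarchy shared across the package."""


class CircalightError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CircalightError):
    """Input file does not conform to the declared dialect (missing column, empty file...)."""


class IntegrityError(CircalightError):
    """Data violate a structural invariant (non-monotonic or duplicated timestamps)."""


class ParameterError(CircalightError, ValueError):
    """A configuration value is outside its admissible domain."""


class InsufficientDataError(CircalightError):
    """Too few unmasked epochs / participants to evaluate the requested quantity."""


class UndefinedIndexError(CircalightError):
    """An index is mathematically undefined for this input (e.g. IS/IV at zero variance)."""


class ResolutionError(CircalightError):
    """Epoch length incompatible with the algorithm (Cole scoring needs 1-min epochs)."""


class UnitError(CircalightError):
    """Data passed on the wrong scale (e.g. log-transformed profile where raw is required)."""


class DegenerateError(CircalightError):
    """A statistic is degenerate for this input (constant outcome, |r| = 1...)."""
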