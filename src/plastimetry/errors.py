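"""Exception hierarchy shared across the pipeline stages."""


class PlastimetryError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PlastimetryError, ValueError):
    """A simulation or analysis parameter violates its invariant."""


class DataError(PlastimetryError, ValueError):
    """Input data are malformed (NaN, missing entries, bad labels)."""


class DegenerateBaselineError(DataError):
    """Raw fluorescence minimum is <= 0, so dF/Fmin is undefined."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class AlignmentError(DataError):
    """Cross-session structures do not share the same identifiers."""


class GeometryError(DataError):
    """A polygon or tree fails a geometric precondition."""


class FormatError(DataError):
    """A file does not conform to its declared format."""


class DesignError(DataError):
    """A factorial design is incomplete (empty cell) or inconsistent."""


class ConfigurationError(PlastimetryError, ValueError):
    """A configuration table or file contains unknown or invalid keys."""


class UndefinedStatisticError(PlastimetryError, ValueError):
    """The requested statistic is undefined on this input (e.g. 0/0 F)."""
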