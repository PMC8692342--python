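"""Exception hierarchy used across the package."""


class GexImputeError(Exception):
    """Base class for all package errors."""


class ParseError(GexImputeError):
    """A delimited-text or SOFT file could not be parsed."""


class FormatError(ParseError):
    """A structured file (e.g. SOFT) is missing required delimiters."""


class NoOverlapError(GexImputeError):
    """Two gene rows share no co-observed sample, so no distance is defined."""


class ParameterError(GexImputeError, ValueError):
    """An algorithm parameter is outside its valid domain."""


class SingularDegreeError(GexImputeError):
    """A normalized Laplacian was requested on a graph with a zero-degree
    vertex.  Drop isolated vertices or enable a degree floor
    (``degree_floor`` argument) to proceed."""


class ContractError(GexImputeError, ValueError):
    """An internal call contract was violated (e.g. non-positive distance
    passed to the inverse-distance weighting)."""


class UnimputableAttributeError(GexImputeError):
    """No gene in the dataset observes the attribute, so nothing can donate
    a value for it."""


class MaskingError(GexImputeError):
    """A missingness-injection request is unsatisfiable."""
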