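"""Exception hierarchy shared by all monomark modules."""


class MonomarkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MonomarkError, ValueError):
    """Unparseable text: a modification tag, a table cell, a BED line."""


class LayoutError(MonomarkError, ValueError):
    """Array layout violates its structural invariants."""


class InvariantError(MonomarkError, ValueError):
    """A domain type's invariant would be violated."""


class GeometryError(MonomarkError, ValueError):
    """Image geometry problem: grid outside raster, polyline off-image."""


class DataError(MonomarkError, ValueError):
    """Bad numeric input, e.g. non-finite pixels."""


class NormalizationError(MonomarkError, ValueError):
    """Normalization impossible, e.g. all-zero array with max scaling."""


class StratificationError(MonomarkError, ValueError):
    """A with/without stratum is empty or too small for a statistic."""


class CorrelationError(MonomarkError, ValueError):
    """Correlation undefined: constant vector or too few observations."""


class CoordinateError(MonomarkError, ValueError):
    """Malformed genomic coordinates (start >= end, negative start)."""


class GenomeError(MonomarkError, ValueError):
    """Inputs refer to incompatible genomes / chromosome sets."""


class InputError(MonomarkError, ValueError):
    """Malformed tabular input, e.g. duplicated gene ids."""


class DesignError(MonomarkError, ValueError):
    """A synthetic-truth design is infeasible as specified."""
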