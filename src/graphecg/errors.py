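"""Exception hierarchy shared across the package."""


class GraphECGError(Exception):
    """Base class for all package errors."""


class FormatError(GraphECGError):
    """A file could not be parsed in its declared format."""


class DataError(GraphECGError):
    """Parsed content violates a data invariant (NaN, ragged leads, ...)."""


class ValidationError(GraphECGError):
    """An argument or configuration value is out of its valid domain."""


class ResolutionError(GraphECGError):
    """Sampling frequency too low to resolve a requested waveform component."""


class NumericError(GraphECGError):
    """A numeric failure (NaN/Inf) occurred inside a computation."""
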