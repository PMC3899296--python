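"""Exception hierarchy shared across the package."""


class EvopoolError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgument(EvopoolError, ValueError):
    """A parameter violates a documented precondition."""


class PoolConflictError(EvopoolError):
    """Two planted variants overlap on the same haplotype."""


class ConfigurationError(EvopoolError):
    """Inputs are mutually inconsistent (e.g. SAM header vs reference)."""


class AnnotationError(EvopoolError):
    """A gene model is inconsistent with the reference sequence."""


class InsufficientDataError(EvopoolError):
    """An estimate is undefined on the given input (e.g. empty pileup column)."""
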