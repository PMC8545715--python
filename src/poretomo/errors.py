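"""Exception hierarchy shared across the package."""


class PoretomoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PoretomoError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(PoretomoError, ValueError):
    """Input is structurally valid but has no usable content (e.g. no pores)."""


class FormatError(PoretomoError, ValueError):
    """An on-disk volume does not satisfy the format contract."""


class EstimationError(PoretomoError, RuntimeError):
    """A regression could not be carried out (too few usable scales)."""


class DescriptorError(PoretomoError, RuntimeError):
    """Spectrum descriptors cannot be formed (reference moment rejected)."""
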