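"""Exception types raised by the decomposition pipeline."""


class ScDecompError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(ScDecompError, ValueError):
    """Bateman time constants outside their admissible domain."""


class TruncationError(ScDecompError, ValueError):
    """Requested kernel duration too short to bound the truncated tail area."""


class SamplingRateError(ScDecompError, ValueError):
    """Signals or kernels with incompatible sample spacing."""


class KernelDomainError(ScDecompError, ValueError):
    """Kernel violates the strict-positivity requirement of the division."""


class InsufficientDataError(ScDecompError, ValueError):
    """Recording too short for the requested statistic."""


class FormatError(ScDecompError, ValueError):
    """Malformed input file (non-monotone or jittered timestamps, bad columns)."""
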