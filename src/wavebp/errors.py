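"""Exception hierarchy shared across the package."""


class WaveBPError(Exception):
    """Base class for all package errors."""


class ParameterError(WaveBPError, ValueError):
    """An argument violated a documented invariant."""


class ConfigError(WaveBPError, ValueError):
    """Inconsistent or invalid configuration."""


class FilterDesignError(WaveBPError):
    """Equiripple design could not meet the requested response."""


class TooShortError(WaveBPError, ValueError):
    """Record too short for the requested operation."""


class DegenerateWindowError(WaveBPError, ValueError):
    """Window has zero variance where variation is required."""


class SplitError(WaveBPError, ValueError):
    """Dataset cannot be partitioned as requested."""


class DivergenceError(WaveBPError, RuntimeError):
    """Training loss became non-finite."""


class FormatError(WaveBPError, ValueError):
    """A file did not match the expected on-disk layout."""


class StateError(WaveBPError, RuntimeError):
    """Operation invoked before required state was fitted/loaded."""
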