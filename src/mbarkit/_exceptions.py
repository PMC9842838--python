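"""Exception hierarchy shared across mbarkit."""


class MbarkitError(Exception):
    """Base class for all mbarkit errors."""


class InputError(MbarkitError, ValueError):
    """Malformed or inconsistent input data (missing columns, ragged files, ...)."""


class ConfigError(MbarkitError, ValueError):
    """Invalid run configuration (mixed modes, missing mode-required fields, ...)."""


class SampleError(MbarkitError, ValueError):
    """Non-finite or otherwise unusable sample values; carries offending indices."""

    def __init__(self, message: str, indices=None):
        super().__init__(message)
        self.indices = indices


class OverlapError(MbarkitError, ValueError):
    """A target state has no configuration-space overlap with the pooled samples."""


class ConvergenceError(MbarkitError, RuntimeError):
    """Iterative solver failed to reach tolerance; carries the residual trace."""

    def __init__(self, message: str, residual_trace=None):
        super().__init__(message)
        self.residual_trace = list(residual_trace) if residual_trace is not None else []
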