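"""Exception hierarchy shared across the package."""


class RippleSyncError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RippleSyncError):
    """Invalid configuration value or schema violation."""


class DataValidationError(RippleSyncError):
    """Input data violates a structural invariant (NaNs, non-monotone time, ...)."""


class DegenerateSignalError(RippleSyncError):
    """A signal is constant or otherwise unusable (sigma == 0)."""


class NyquistError(RippleSyncError):
    """Requested analysis band is not supported by the sampling rate."""


class DegenerateInputError(RippleSyncError):
    """Regression input is rank deficient or all-zero."""
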