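"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value is invalid or inconsistent."""


class DataError(ValueError):
    """Input data violate a structural requirement (dates, alignment, ...)."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""
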