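"""Exception types raised across the package."""


class FormatError(ValueError):
    """A tabular input file violates the expected dialect or schema."""


class CalibrationError(RuntimeError):
    """A spike-in calibration curve cannot be fitted (fewer than two
    detected standards in the requested replicate)."""


class ConfigError(ValueError):
    """Run configuration is inconsistent (bad thresholds, missing sample
    roles, unknown machinery class, ...)."""
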