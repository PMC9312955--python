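"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
anything else -> 4.
"""


class MViTEEGError(Exception):
    """Base class for package errors."""


class ConfigError(MViTEEGError):
    """Invalid configuration (bad field value, violated invariant, unknown key)."""


class DataError(MViTEEGError):
    """Invalid or unreadable input data (files, labels, shapes)."""


class TrainingError(MViTEEGError):
    """Training failed (single-class data, divergence)."""
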