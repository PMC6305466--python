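"""Exception hierarchy.

``InputError`` covers malformed or inconsistent input data, ``ConfigError``
invalid parameter settings, ``NumericalError`` failures arising during
computation (degenerate designs, empty selections, ...). The CLI maps each
class to a distinct exit code.
"""


class EEGWorkloadError(Exception):
    """Base class for all package errors."""


class InputError(EEGWorkloadError):
    """Malformed, missing or inconsistent input data."""


class ConfigError(EEGWorkloadError):
    """Invalid configuration values."""


class NumericalError(EEGWorkloadError):
    """Degenerate or unsolvable numerical situation."""
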