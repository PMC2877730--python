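"""Exception hierarchy. Everything raised on bad user input derives from InputError."""


class PeptiquantError(Exception):
    """Base class for all package errors."""


class InputError(PeptiquantError, ValueError):
    """Invalid argument or malformed input data."""


class ProcessingError(PeptiquantError):
    """A prohormone-processing or spectrum-processing step cannot proceed."""


class QuantificationError(PeptiquantError):
    """Quantification impossible (e.g. internal standard not detected)."""


class ConfigError(InputError):
    """Run configuration is invalid (unknown key, missing seed, bad value)."""
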