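"""Exception types shared across the pipeline."""


class WardsenseError(Exception):
    """Base class for all package errors."""


class ConfigError(WardsenseError):
    """An invalid configuration value; the message names the field."""


class FormatError(WardsenseError):
    """A log file does not match the expected delimited-text dialect."""


class ValidationError(WardsenseError):
    """Inputs are mutually inconsistent (roster, schedule, wear log...)."""


class ComputationError(WardsenseError):
    """A numerical routine failed to converge or produced invalid output."""
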