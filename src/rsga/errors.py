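"""Exception hierarchy shared across the pipeline.

Each class carries the process exit code the command-line layer maps it to.
"""


class RsgaError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigurationError(RsgaError):
    """Invalid configuration value; the message names the offending field."""

    exit_code = 2


class DataIntegrityError(RsgaError):
    """Input data violate a structural contract (duplicates, bad bounds...)."""

    exit_code = 3


class FileFormatError(RsgaError):
    """A file could not be parsed as the expected format."""

    exit_code = 4
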