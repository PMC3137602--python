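"""Exception hierarchy with distinct CLI exit codes.

Exit code convention: 2 = configuration error (bad flags/parameters),
3 = data error (malformed or inconsistent input files), 4 = computation
error (a stage failed on valid-looking input).
"""


class RfetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RfetError):
    """Invalid parameter or configuration value."""

    exit_code = 2


class DataError(RfetError):
    """Malformed, inconsistent, or missing input data."""

    exit_code = 3


class ComputationError(RfetError):
    """A pipeline stage failed during computation."""

    exit_code = 4
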