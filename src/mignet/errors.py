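"""Exception hierarchy.

Each class maps to a CLI exit code: ConfigError -> 2, InputError (and
its ParseError subclass) -> 3, ContractViolation -> 4.
"""


class MignetError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(MignetError):
    """Invalid configuration value, schema violation or infeasible spec."""

    exit_code = 2


class InputError(MignetError):
    """Missing or unreadable input file, or invalid input data."""

    exit_code = 3


class ParseError(InputError):
    """Malformed rows or unmappable vocabulary in an input table."""


class DegenerateInputError(InputError):
    """Numerically degenerate input (e.g. zero group mean with zero pseudocount)."""


class ContractViolation(MignetError):
    """An internal precondition was violated by a caller."""

    exit_code = 4
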