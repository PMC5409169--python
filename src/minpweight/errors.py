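"""Exception hierarchy; each class maps to a distinct CLI exit code."""


class MinpWeightError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(MinpWeightError):
    """Malformed or invalid input data (bad masses, weeks, parse failures)."""

    exit_code = 2


class ConfigError(MinpWeightError):
    """Invalid configuration: unknown arm labels, bad parameters, bad specs."""

    exit_code = 3


class ProcedureError(MinpWeightError):
    """A statistical procedure cannot run on the given inputs."""

    exit_code = 4


class InsufficientDataError(ProcedureError):
    """Too few observations for a test (e.g. n < 2 on one side)."""
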