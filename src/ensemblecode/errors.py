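"""Exception types shared across the pipeline."""


class EnsemblecodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EnsemblecodeError):
    """A configuration value is invalid; the message names the field."""


class ScheduleError(EnsemblecodeError):
    """A trial window is inconsistent with the recorded trace or schedule."""


class CorruptInputError(EnsemblecodeError):
    """Input data violates a basic well-formedness contract (NaNs, unsorted)."""


class UndefinedValueError(EnsemblecodeError):
    """A statistic is undefined for the given input (e.g. zero-variance vector)."""


class InsufficientTrialsError(EnsemblecodeError):
    """Too few trials of some condition; the message names the condition."""


class IncompleteProfileError(EnsemblecodeError):
    """A neuron profile is missing a contrast needed for categorization."""
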