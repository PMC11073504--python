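"""Exception hierarchy shared across the package."""


class HallmarkTasksError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HallmarkTasksError):
    """An argument or configuration field is invalid; the message names the field."""


class FormatError(HallmarkTasksError):
    """An input file violates the expected format or an invariant of its type."""


class AnalysisError(HallmarkTasksError):
    """The data do not meet the preconditions of a statistical operation."""
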