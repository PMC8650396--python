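"""Exception hierarchy shared by all modules."""


class MethylBenchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MethylBenchError, ValueError):
    """A configuration object or parameter is invalid."""


class ValidationError(MethylBenchError, ValueError):
    """Input data violates a documented precondition."""


class BedGraphParseError(MethylBenchError, ValueError):
    """A bedGraph line could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
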