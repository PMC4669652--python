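"""Exception hierarchy.

``UsageError`` signals a caller mistake (bad parameter, mismatched inputs),
``FormatError`` a malformed input file, ``GenerationError`` an infeasible
synthetic-data request, and ``SamplingError`` an exhausted rejection sampler.
The CLI maps these onto its documented exit codes.
"""


class PeaklabError(Exception):
    """Base class for all package-specific errors."""


class UsageError(PeaklabError, ValueError):
    """The caller violated a precondition (bad arguments, mismatched inputs)."""


class FormatError(PeaklabError, ValueError):
    """An input file or text block does not conform to its declared format."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigError(PeaklabError, ValueError):
    """A run configuration is invalid or references missing inputs."""


class GenerationError(PeaklabError, RuntimeError):
    """A synthetic-data request cannot be satisfied (e.g. no genome space)."""


class SamplingError(PeaklabError, RuntimeError):
    """A rejection sampler exhausted its draw budget."""

    def __init__(self, message: str, bin_label: str | None = None):
        self.bin_label = bin_label
        super().__init__(message)
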