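"""Exception hierarchy shared across the pipeline stages."""


class TojlabError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TojlabError):
    """A tabular input does not match the documented file format."""


class ValidationError(TojlabError):
    """Records violate a data-model invariant (counts, sign rules, cells)."""


class ParameterError(TojlabError):
    """A caller-supplied parameter is outside its documented range."""


class DomainError(TojlabError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FitError(TojlabError):
    """The psychometric fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateInputError(TojlabError):
    """A sample is too small or constant for the requested statistic."""
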