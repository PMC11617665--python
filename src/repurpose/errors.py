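"""Exception hierarchy shared across the pipeline stages."""


class RepurposeError(Exception):
    """Base class for all package-specific errors."""


class EmptyLibraryError(RepurposeError):
    """A parsed library contained zero usable records."""


class StructureError(RepurposeError):
    """A molecular structure could not be parsed or processed."""


class ParameterError(RepurposeError, ValueError):
    """An operation was called with inconsistent or out-of-range parameters."""


class DomainError(RepurposeError, ValueError):
    """A model was evaluated outside its mathematical domain."""


class DegenerateRangeError(RepurposeError):
    """Score normalization is undefined because all scores are identical."""


class FitError(RepurposeError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class FlatDataError(FitError):
    """Dose-response data carry no usable concentration dependence."""
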