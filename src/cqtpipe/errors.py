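"""Exception types shared across the pipeline stages."""


class CqtPipeError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(CqtPipeError):
    """Input table or value failed schema/unit/range validation."""


class ConfigError(CqtPipeError):
    """Pipeline or generator configuration is inconsistent or incomplete."""


class InsufficientDataError(CqtPipeError):
    """Not enough observations to perform the requested computation."""


class SingularFitError(CqtPipeError):
    """Design is degenerate (e.g. all RR intervals identical)."""


class DegenerateParameterError(CqtPipeError):
    """Model parameters at a degenerate point (e.g. ka == ke)."""


class FitError(CqtPipeError):
    """A model fit failed to converge; carries diagnostics in the message."""
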