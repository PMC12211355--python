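"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A simulation or weighting configuration is internally inconsistent."""


class ValidationError(ValueError):
    """Input data violate a documented precondition."""


class SchemaError(KeyError):
    """A required variable is absent from the input frame."""


class DegenerateOutcomeError(ValueError):
    """The outcome has a single class; a logistic model cannot be fitted."""


class RakingError(RuntimeError):
    """Iterative proportional fitting cannot converge (e.g. empty margin cell)."""


class EstimationError(RuntimeError):
    """A model fit failed to converge or produced unusable estimates."""
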