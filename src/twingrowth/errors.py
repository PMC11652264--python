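"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant."""


class SpecError(ValueError):
    """Raised for invalid model or simulation specifications."""


class DegenerateDesignError(ValueError):
    """Raised when a regression design is degenerate (e.g. constant ages)."""


class IdentificationError(ValueError):
    """Raised when a model is structurally unidentified before fitting."""


class NotNestedError(ValueError):
    """Raised when a likelihood-ratio test is requested for non-nested fits."""
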