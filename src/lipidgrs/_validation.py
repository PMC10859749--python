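"""Shared exception types."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class CollinearityError(ValidationError):
    """A regression design matrix is rank-deficient.

    Carries the names of the offending columns in ``columns``.
    """

    def __init__(self, columns):
        self.columns = tuple(columns)
        super().__init__(
            "design matrix is rank-deficient; linearly dependent columns: "
            + ", ".join(self.columns)
        )


class OrientationError(ValidationError):
    """A risk-allele orientation is undefined (zero estimated effect)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names where."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
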