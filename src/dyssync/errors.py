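"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a structural or physiological invariant
    (wrong segment count, non-monotone time grid, negative volumes, ...)."""


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the given data
    (single-class cohort, zero variance, empty group, ...)."""
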