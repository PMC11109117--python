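"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class NoLesionError(ValueError):
    """Raised when a score ratio is requested for an image with zero lesional area.

    The total-score entry points catch this and return the degenerate
    breakdown (V = epsilon) instead; callers of the low-level ratio
    functions must handle it explicitly.
    """
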