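"""Exception and warning types shared across the package."""


class ParencliticError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(ParencliticError, ValueError):
    """A dataset or run specification violates its invariants."""


class InsufficientDataError(ParencliticError, ValueError):
    """Too few samples to fit the requested model."""


class DegenerateFitError(ParencliticError, ValueError):
    """The data admit no meaningful fit (e.g. zero spread in a coordinate)."""


class InvalidLabelsError(ParencliticError, ValueError):
    """Class labels do not satisfy the fitting preconditions."""


class SchemaError(ParencliticError, ValueError):
    """A table is missing required columns or contains non-numeric values."""


class DegeneracyWarning(UserWarning):
    """A degenerate model was substituted (constant-zero edge weight)."""
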