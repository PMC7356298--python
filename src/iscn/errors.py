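"""Exception hierarchy shared across the package."""


class ISCNError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ISCNError):
    """A file or table does not have the expected structure."""


class ValidationError(ISCNError):
    """Data violates an invariant (non-positive thickness, asymmetry, ...)."""


class DegenerateInputError(ISCNError):
    """Input is structurally valid but statistically degenerate
    (zero variance, rank-deficient design, too few observations)."""
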