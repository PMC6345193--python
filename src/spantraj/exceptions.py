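"""Exception hierarchy used across the package."""


class SpanTrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpanTrajError, ValueError):
    """Invalid engine, cohort or pipeline configuration."""


class BoundsError(SpanTrajError, ValueError):
    """A sequence length outside the configured [min_length, max_length]."""


class UsageError(SpanTrajError, ValueError):
    """An operation called with arguments that violate its contract."""


class StructuralError(SpanTrajError, ValueError):
    """An administration record whose trial structure is malformed."""


class EnumerationSizeError(SpanTrajError, ValueError):
    """Exhaustive response-pattern enumeration would be too large."""


class ParameterError(SpanTrajError, ValueError):
    """Invalid statistical/generative parameter (e.g. non-PD correlation)."""


class MissingDataError(SpanTrajError, ValueError):
    """Required condition scores or columns are absent for a participant."""


class SchemaError(SpanTrajError, ValueError):
    """An input table does not match the expected column schema."""


class GroupingError(SpanTrajError, ValueError):
    """A required group (e.g. MBID) is empty after filtering."""


class SingularDesignError(SpanTrajError, ValueError):
    """Rank-deficient design matrix; names the collinear terms."""
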