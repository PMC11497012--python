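"""Exception hierarchy for the illness-death projection pipeline."""


class IdmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IdmError, ValueError):
    """Invalid generator/pipeline configuration."""


class CoverageError(IdmError, ValueError):
    """A schedule or panel does not cover a required (measure, year) range."""


class AlignmentError(IdmError, ValueError):
    """Two keyed collections do not share keys/years."""


class DegenerateCohortError(IdmError, ValueError):
    """Cohort reached a degenerate state (extinct or fully prevalent)."""


class InconsistentRatesError(IdmError, ValueError):
    """Observed rates violate a structural constraint (e.g. cause > all-cause)."""


class SchemaError(IdmError, ValueError):
    """A table is missing a required column or has a malformed layout."""
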