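"""Exception hierarchy shared across the package."""


class SnpMetaError(Exception):
    """Base class for all package errors."""


class SchemaError(SnpMetaError):
    """Input table header does not match the column contract."""


class ValidationError(SnpMetaError):
    """A data row violates a field invariant (carries study_id when known)."""


class EstimationError(SnpMetaError):
    """An effect cannot be estimated (e.g. an empty study arm)."""


class InsufficientStudiesError(SnpMetaError):
    """Too few studies for the requested statistic."""


class HeterogeneityUndefinedError(SnpMetaError):
    """Cochran's Q requires at least two studies (df = k - 1 > 0)."""


class DegenerateTableError(SnpMetaError):
    """Contingency table has a zero marginal row or column."""
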