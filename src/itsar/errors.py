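"""Exception hierarchy for the itsar package.

All package-specific failures derive from :class:`ItsarError` so callers can
catch one base class at pipeline boundaries.
"""


class ItsarError(Exception):
    """Base class for all itsar errors."""


class SchemaError(ItsarError):
    """A required column is missing or the column mapping is invalid."""


class DataError(ItsarError):
    """The input rows violate panel constraints (e.g. duplicated months)."""


class GapError(DataError):
    """A group's months are not consecutive; the message names the first gap."""


class CoverageError(ItsarError):
    """The series does not span the requested study window."""


class IdentifiabilityError(ItsarError):
    """The design cannot identify the requested parameters."""


class SingularDesignError(ItsarError):
    """The design matrix is rank deficient."""


class StationarityError(ItsarError):
    """Estimated AR parameters imply a nonstationary error process."""


class OverparameterizationError(ItsarError):
    """No residual degrees of freedom remain after fitting."""


class DomainError(ItsarError):
    """An argument is outside the mathematical domain of an operation."""


class CounterfactualDomainError(DomainError):
    """An extrapolated baseline rate is non-positive, so percentage change
    is undefined."""


class BootstrapInstabilityError(ItsarError):
    """Too many bootstrap refits failed for the resampling distribution to
    be trusted."""
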