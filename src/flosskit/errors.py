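"""Exception hierarchy shared across the package."""


class FlossKitError(Exception):
    """Base class for all package-specific errors."""


class PedigreeFormatError(FlossKitError, ValueError):
    """Structural problem with a pedigree file (missing column, bad header)."""


class PedigreeDataError(FlossKitError, ValueError):
    """Row-level data problem (duplicate id, unparsable year)."""


class CohortRangeError(FlossKitError, ValueError):
    """Birth year outside every configured cohort band."""


class LifeTableFormatError(FlossKitError, ValueError):
    """Malformed life-table file (non-monotone survival, missing base-age row)."""


class EmptyStratumError(FlossKitError, ValueError):
    """No usable individuals in a sex/birth-cohort stratum."""


class ConditioningError(FlossKitError, ValueError):
    """Conditioning a survival function at an age where it is zero."""


class ScoreError(FlossKitError, ValueError):
    """Base class for scoring problems."""


class TableMismatchError(ScoreError):
    """Individual scored against a table of the wrong sex or cohort band."""


class EligibilityError(ScoreError):
    """Individual not score-eligible (attained age below the base age)."""


class EmptySibshipError(ScoreError):
    """Sibship with no scoreable member."""


class DegenerateSummaryError(ScoreError):
    """Score summary undefined (fewer than two sibships, or zero spread)."""


class StudyConfigError(FlossKitError, ValueError):
    """Invalid study configuration."""
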