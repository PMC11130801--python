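"""Named error types raised across the package.

Every user-facing failure mode gets its own class so the CLI can surface a
one-line remedy hint per error instead of a generic traceback.
"""


class CohortBalanceError(Exception):
    """Base class for all package errors."""


class UnreadableFileError(CohortBalanceError):
    """The input file does not exist or cannot be parsed at all."""


class RaggedRowsError(CohortBalanceError):
    """A CSV row has a different number of cells than the header."""


class EmptyTableError(CohortBalanceError):
    """The parsed table has no data rows or no columns."""


class UnknownColumnError(CohortBalanceError):
    """A named column does not exist in the table."""


class DuplicateIdentifierError(CohortBalanceError):
    """The identifier column contains repeated or missing values."""


class TargetCardinalityError(CohortBalanceError):
    """The target variable has fewer than 2 or more than 15 subpopulations."""


class RoleConflictError(CohortBalanceError):
    """The same column was assigned to both the identifier and target roles."""


class AllMissingError(CohortBalanceError):
    """A variable has no non-missing values to impute from."""


class DegenerateSampleError(CohortBalanceError):
    """A statistical test's preconditions fail (too few values, zero variance)."""


class ContingencyError(CohortBalanceError):
    """A contingency table is malformed (zero margin, wrong shape)."""


class ConfigError(CohortBalanceError):
    """An equalization or CLI configuration is invalid."""


class ProtectedIdError(CohortBalanceError):
    """A protected identifier does not exist in the table."""


class ThresholdError(CohortBalanceError):
    """MinThreshold exceeds the smallest subpopulation, forbidding progress."""


class ReportIntegrityError(CohortBalanceError):
    """The kept/removed partition failed the sanity check."""
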