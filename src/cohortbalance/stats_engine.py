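"""Automated hypothesis-test selection and descriptive summaries.

The dispatch rule mirrors standard biostatistical practice for comparing a
feature across target subpopulations:

* categorical feature -> chi-square test of independence on the contingency
  table (Yates continuity correction for 2x2), falling back to Fisher's exact
  test when a 2x2 table has any expected cell count below 5 (Cochran rule);
* continuous feature  -> Shapiro–Wilk normality gate at p > 0.05, then
  Welch t-test / Mann–Whitney U for two groups, one-way ANOVA with Tukey HSD /
  Kruskal–Wallis with Dunn–Bonferroni for three or more.

All inferential machinery comes from scipy/statsmodels except Dunn's post hoc
test, which is computed here from the pooled mid-ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import CohortTable, VariableSpec
from .errors import ContingencyError, DegenerateSampleError

NORMALITY_ALPHA = 0.05
EXPECTED_COUNT_MIN = 5.0  # Cochran applicability bound for the chi-square
EXACT_MWU_MAX_N = 8  # exact U distribution when min(n) <= this and no ties


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of feature categories (rows) across subpopulations (columns)."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray  # shape (len(row_labels), len(col_labels))

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ContingencyError("counts shape does not match labels")
        if (c < 0).any() or c.sum() == 0:
            raise ContingencyError("counts must be non-negative with total > 0")

    @property
    def expected(self) -> np.ndarray:
        c = self.counts.astype(float)
        return np.outer(c.sum(axis=1), c.sum(axis=0)) / c.sum()


@dataclass(frozen=True)
class TestResult:
    variable: str
    test_name: str
    statistic: float
    p_value: float
    normality_p: float | None = None
    posthoc: tuple = ()  # ((group_a, group_b), p) pairs
    warnings: tuple = ()


@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-group descriptives: counts/proportions for categorical variables,
    median with the 25th–75th percentile interval for continuous ones."""

    variable: str
    kind: str
    per_group: dict  # label -> list[(category, count, proportion)] | dict


def build_contingency(
    table: CohortTable, variable: str
) -> ContingencyTable:
    """Cross-tabulate a categorical feature against the target; rows with a
    missing cell in either column are dropped."""
    df = table.df[[variable, table.target_column]].dropna()
    ct = pd.crosstab(df[variable], df[table.target_column])
    ct = ct.sort_index(axis=0, key=lambda ix: ix.map(str))
    ct = ct.sort_index(axis=1, key=lambda ix: ix.map(str))
    return ContingencyTable(
        row_labels=tuple(ct.index),
        col_labels=tuple(ct.columns),
        counts=ct.to_numpy(),
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p; undefined for n < 3 or a constant sample."""
    arr = np.asarray([float(v) for v in values if not pd.isna(v)])
    if len(arr) < 3:
        raise DegenerateSampleError(f"Shapiro–Wilk needs n >= 3, got {len(arr)}")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("Shapiro–Wilk undefined for a constant sample")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def chi_square_test(ct: ContingencyTable, variable: str = "") -> TestResult:
    """Pearson chi-square of independence; Yates-corrected when 2x2."""
    counts = ct.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ContingencyError("contingency table has a zero margin")
    is_2x2 = counts.shape == (2, 2)
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=is_2x2)
    return TestResult(
        variable=variable, test_name="chi_square",
        statistic=float(chi2), p_value=float(p),
    )


def fisher_exact(ct: ContingencyTable, variable: str = "") -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (sum of hypergeometric
    probabilities of tables at most as probable as the observed one)."""
    if ct.counts.shape != (2, 2):
        raise ContingencyError("Fisher's exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(ct.counts, alternative="two-sided")
    return TestResult(
        variable=variable, test_name="fisher_exact",
        statistic=float(odds), p_value=float(p),
    )


def t_test_independent(a, b, variable: str = "", normality_p=None) -> TestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateSampleError("t-test needs n >= 2 in each group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TestResult(variable, "t_test", 0.0, 1.0, normality_p)
        raise DegenerateSampleError("t-test undefined: both groups constant")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(variable, "t_test", float(t), float(p), normality_p)


def mann_whitney_u(a, b, variable: str = "", normality_p=None) -> TestResult:
    """Two-sided Mann–Whitney U.

    The exact null distribution is used for small tie-free samples
    (min(n) <= 8); otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateSampleError("Mann–Whitney U needs non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= EXACT_MWU_MAX_N and not has_ties) \
        else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(variable, "mann_whitney_u", float(u), float(p),
                      normality_p, warnings=(f"null_distribution={method}",))


def anova_oneway(groups: dict, variable: str = "", normality_p=None) -> TestResult:
    """One-way ANOVA across >= 3 groups, with Tukey HSD pairwise post hoc."""
    labels = sorted(groups, key=str)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 3:
        raise DegenerateSampleError("one-way ANOVA here requires >= 3 groups")
    if any(len(s) < 2 for s in samples):
        raise DegenerateSampleError("ANOVA needs n >= 2 in every group")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return TestResult(variable, "anova", 0.0, 1.0, normality_p)
    f, p = stats.f_oneway(*samples)
    if np.isnan(f):  # identical group means with zero within-group variance
        f, p = 0.0, 1.0
    posthoc = _tukey_posthoc(labels, samples)
    return TestResult(variable, "anova", float(f), float(p), normality_p, posthoc)


def _tukey_posthoc(labels, samples) -> tuple:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(samples)
    if np.ptp(values) == 0:
        return tuple(((a, b), 1.0) for a, b in itertools.combinations(labels, 2))
    tags = np.concatenate([
        np.repeat(str(lbl), len(s)) for lbl, s in zip(labels, samples)
    ])
    res = pairwise_tukeyhsd(values, tags)
    by_str = {str(lbl): lbl for lbl in labels}
    out = []
    for row, p in zip(res._results_table.data[1:], res.pvalues):
        out.append(((by_str[str(row[0])], by_str[str(row[1])]), float(p)))
    return tuple(out)


def kruskal_wallis(groups: dict, variable: str = "", normality_p=None) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn–Bonferroni post hoc."""
    labels = sorted(groups, key=str)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 3:
        raise DegenerateSampleError("Kruskal–Wallis here requires >= 3 groups")
    if any(len(s) == 0 for s in samples):
        raise DegenerateSampleError("Kruskal–Wallis needs non-empty groups")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        # H undefined when every observation is identical
        posthoc = tuple(
            ((a, b), 1.0) for a, b in itertools.combinations(labels, 2)
        )
        return TestResult(variable, "kruskal_wallis", 0.0, 1.0, normality_p, posthoc)
    h, p = stats.kruskal(*samples)
    posthoc = dunn_posthoc(groups)
    return TestResult(
        variable, "kruskal_wallis", float(h), float(p), normality_p, posthoc
    )


def dunn_posthoc(groups: dict) -> tuple:
    """Dunn's pairwise z-tests on mean mid-ranks, Bonferroni-adjusted.

    Variance uses the tie-corrected form N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    labels = sorted(groups, key=str)
    samples = {g: np.asarray(groups[g], dtype=float) for g in labels}
    pooled = np.concatenate([samples[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        n = len(samples[g])
        mean_ranks[g] = ranks[start:start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)  # Bonferroni
        out.append(((a, b), float(p)))
    return tuple(out)


def select_test(spec: VariableSpec, table: CohortTable) -> TestResult:
    """Dispatch to the appropriate test for one feature variable.

    Missing cells in the feature or target are dropped pairwise before
    testing (run after imputation in the normal pipeline, so usually none).
    """
    if spec.role != "feature":
        raise DegenerateSampleError(f"{spec.name!r} is not a feature variable")
    df = table.df[[spec.name, table.target_column]].dropna()
    group_labels = sorted(df[table.target_column].unique(), key=str)
    if len(group_labels) < 2:
        raise DegenerateSampleError("fewer than 2 subpopulations after dropping NA")

    if spec.kind == "categorical":
        ct = build_contingency(table, spec.name)
        if len(ct.row_labels) < 2:
            raise DegenerateSampleError(
                f"{spec.name!r} is constant across all subpopulations"
            )
        expected = ct.expected
        if ct.counts.shape == (2, 2) and (expected < EXPECTED_COUNT_MIN).any():
            return fisher_exact(ct, variable=spec.name)
        result = chi_square_test(ct, variable=spec.name)
        if ct.counts.shape != (2, 2) and (expected < EXPECTED_COUNT_MIN).any():
            result = TestResult(
                **{**result.__dict__,
                   "warnings": ("low_expected_counts",)},
            )
        return result

    # continuous: pooled normality gate, then group-count dispatch
    values = df[spec.name].astype(float)
    if values.nunique() == 1:
        raise DegenerateSampleError(
            f"{spec.name!r} is constant across all subpopulations"
        )
    _, norm_p = shapiro_wilk(values)
    by_group = {
        g: df.loc[df[table.target_column] == g, spec.name].astype(float).to_numpy()
        for g in group_labels
    }
    if len(group_labels) == 2:
        a, b = (by_group[g] for g in group_labels)
        if norm_p > NORMALITY_ALPHA:
            return t_test_independent(a, b, spec.name, normality_p=norm_p)
        return mann_whitney_u(a, b, spec.name, normality_p=norm_p)
    if norm_p > NORMALITY_ALPHA:
        return anova_oneway(by_group, spec.name, normality_p=norm_p)
    return kruskal_wallis(by_group, spec.name, normality_p=norm_p)


def describe(spec: VariableSpec, table: CohortTable) -> DescriptiveSummary:
    """Per-subpopulation descriptive summary of one variable.

    Categorical: (category, count, proportion) per group.  Continuous:
    median, 25th/75th percentiles (linear interpolation) and the IQR width.
    """
    df = table.df[[spec.name, table.target_column]].dropna()
    per_group: dict = {}
    for g in sorted(df[table.target_column].unique(), key=str):
        sub = df.loc[df[table.target_column] == g, spec.name]
        if spec.kind == "categorical":
            counts = sub.value_counts()
            counts = counts.sort_index(key=lambda ix: ix.map(str))
            total = int(counts.sum())
            per_group[g] = [
                (cat, int(n), int(n) / total) for cat, n in counts.items()
            ]
        else:
            arr = sub.astype(float).to_numpy()
            p25, p50, p75 = np.percentile(arr, [25, 50, 75])
            per_group[g] = {
                "median": float(p50), "p25": float(p25), "p75": float(p75),
                "iqr_width": float(p75 - p25), "n": len(arr),
            }
    return DescriptiveSummary(variable=spec.name, kind=spec.kind, per_group=per_group)


def format_p(p: float) -> str:
    """Display rule: 3 decimals; values below 0.0005 render as ``<0.001``."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"
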