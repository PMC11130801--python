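"""Automated test selection, the individual tests, and descriptive summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cohortbalance import (
    CohortTable,
    ContingencyTable,
    anova_oneway,
    build_contingency,
    chi_square_test,
    describe,
    fisher_exact,
    infer_variable_types,
    kruskal_wallis,
    mann_whitney_u,
    select_test,
    shapiro_wilk,
    t_test_independent,
    validate_roles,
)
from cohortbalance.errors import ContingencyError, DegenerateSampleError
from cohortbalance.stats_engine import dunn_posthoc, format_p
from oracles import fisher_two_sided_enumeration, mwu_exact_two_sided_enumeration


def _cohort_from_counts(counts: dict) -> CohortTable:
    """Build a two-column cohort realizing exact (feature, group) counts."""
    rows = []
    i = 0
    for (feat, grp), n in counts.items():
        for _ in range(n):
            rows.append((f"s{i:04d}", grp, feat))
            i += 1
    df = pd.DataFrame(rows, columns=["id", "group", "feat"], dtype=object)
    return validate_roles(CohortTable(df=df), target="group", identifier="id")


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([3.0] * 10)

    def test_too_small_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([1.0, 2.0])

    def test_bell_shaped_sample_classified_normal(self):
        rng = np.random.default_rng(5)
        w, p = shapiro_wilk(rng.normal(size=100))
        assert 0 < w <= 1 and p > 0.05

    def test_exponential_sample_classified_non_normal(self):
        rng = np.random.default_rng(5)
        _, p = shapiro_wilk(rng.exponential(size=100))
        assert p < 0.05


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts,expected_p",
        [
            ([[89, 23], [79, 24]], 0.745),
            ([[44, 68], [40, 63]], 1.000),
            ([[36, 76], [33, 70]], 1.000),
            ([[104, 8], [95, 8]], 1.000),
        ],
    )
    def test_yates_corrected_two_by_two(self, counts, expected_p):
        """The continuity-corrected p on published COVID/control 2x2 tables."""
        ct = ContingencyTable(("no", "yes"), ("covid", "control"),
                              np.array(counts))
        res = chi_square_test(ct)
        assert round(res.p_value, 3) == expected_p

    def test_balanced_table_statistic_zero(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 10], [10, 10]]))
        res = chi_square_test(ct)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_larger_tables_uncorrected(self):
        counts = np.array([[20, 30], [25, 22], [28, 27]])
        ct = ContingencyTable(("a", "b", "c"), ("x", "y"), counts)
        res = chi_square_test(ct)
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)

    def test_zero_margin_rejected(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), np.array([[0, 0], [5, 5]]))
        with pytest.raises(ContingencyError):
            chi_square_test(ct)


class TestFisherExact:
    def test_modal_table_p_one(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), np.array([[5, 5], [5, 5]]))
        assert fisher_exact(ct).p_value == 1.0

    def test_two_table_margin_space(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), np.array([[1, 0], [0, 1]]))
        assert fisher_exact(ct).p_value == 1.0

    def test_matches_enumeration_on_skewed_table(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), np.array([[8, 2], [1, 9]]))
        oracle = fisher_two_sided_enumeration(8, 2, 1, 9)
        assert fisher_exact(ct).p_value == pytest.approx(oracle, abs=1e-10)

    def test_non_2x2_rejected(self):
        ct = ContingencyTable(("a", "b", "c"), ("x", "y"),
                              np.array([[1, 2], [3, 4], [5, 6]]))
        with pytest.raises(ContingencyError):
            fisher_exact(ct)


class TestTTest:
    def test_identical_samples(self):
        res = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_shift_significant_and_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        res = t_test_independent(a, b)
        # equal variances, equal n: Welch t coincides with the pooled t
        t_closed = (np.mean(a) - np.mean(b)) / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t_closed)
        assert res.p_value < 0.01

    def test_swap_flips_sign_not_p(self):
        a, b = [1.0, 4.0, 2.0], [3.0, 6.0, 8.0]
        r1, r2 = t_test_independent(a, b), t_test_independent(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestMannWhitney:
    def test_tied_identical_samples_p_one(self):
        assert mann_whitney_u([1.0, 2.0], [1.0, 2.0]).p_value == 1.0

    def test_no_overlap_exact_tail(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.p_value == pytest.approx(2 / 252)

    def test_label_swap_invariant(self):
        a, b = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0, 4.0]
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value
        )

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for na, nb in [(2, 3), (4, 4), (5, 6), (6, 6)]:
            pooled = rng.permutation(np.arange(1, na + nb + 1, dtype=float))
            a, b = pooled[:na], pooled[na:]
            oracle = mwu_exact_two_sided_enumeration(list(a), list(b))
            assert mann_whitney_u(a, b).p_value == pytest.approx(oracle, abs=1e-12)


class TestAnova:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = anova_oneway(g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_group_significant_with_closed_form_f(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [21.0, 22.0, 23.0]}
        res = anova_oneway(g)
        samples = [np.array(g[k]) for k in sorted(g)]
        grand = np.mean(np.concatenate(samples))
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        f_closed = (ss_between / 2) / (ss_within / 6)
        assert res.statistic == pytest.approx(f_closed)
        assert res.p_value < 0.01
        # only pairs involving the shifted group are significant in Tukey
        for (x, y), p in res.posthoc:
            if "c" in (x, y):
                assert p < 0.05
            else:
                assert p > 0.05

    def test_group_order_invariance(self):
        g = {"a": [1.0, 5.0], "b": [2.0, 6.0], "c": [9.0, 4.0]}
        g_perm = {"c": g["c"], "a": g["a"], "b": g["b"]}
        assert anova_oneway(g).statistic == pytest.approx(
            anova_oneway(g_perm).statistic
        )

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateSampleError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0], "c": [3.0, 4.0]})


class TestKruskalWallis:
    def test_identical_observations_p_one(self):
        res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_h_matches_brute_force_ranks(self):
        g = {"a": [1.0, 7.0], "b": [3.0, 5.0], "c": [2.0, 9.0, 11.0]}
        res = kruskal_wallis(g)
        pooled = sorted(v for vs in g.values() for v in vs)
        rank = {v: i + 1 for i, v in enumerate(pooled)}
        n = len(pooled)
        h = 12.0 / (n * (n + 1)) * sum(
            len(vs) * (np.mean([rank[v] for v in vs]) - (n + 1) / 2) ** 2
            for vs in g.values()
        )
        assert res.statistic == pytest.approx(h)

    def test_bonferroni_dunn_at_least_raw(self):
        g = {"a": [1.0, 7.0, 3.0], "b": [3.5, 5.0, 6.0], "c": [2.0, 9.0, 11.0]}
        adjusted = dict(dunn_posthoc(g))
        # recompute the raw (unadjusted) Dunn p for each pair
        pooled = np.concatenate([g[k] for k in sorted(g)])
        ranks = stats.rankdata(pooled)
        offsets, mean_ranks = 0, {}
        for k in sorted(g):
            mean_ranks[k] = ranks[offsets:offsets + len(g[k])].mean()
            offsets += len(g[k])
        n = len(pooled)
        _, t = np.unique(pooled, return_counts=True)
        var = n * (n + 1) / 12 - np.sum(t ** 3 - t) / (12 * (n - 1))
        for (x, y), p_adj in adjusted.items():
            se = np.sqrt(var * (1 / len(g[x]) + 1 / len(g[y])))
            raw = 2 * stats.norm.sf(abs(mean_ranks[x] - mean_ranks[y]) / se)
            assert p_adj >= raw - 1e-12


class TestSelectTest:
    def test_categorical_large_counts_use_chi_square(self):
        t = _cohort_from_counts({("f", "case"): 44, ("m", "case"): 68,
                                 ("f", "ctrl"): 40, ("m", "ctrl"): 63})
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        assert select_test(spec, t).test_name == "chi_square"

    def test_low_expected_counts_fall_back_to_fisher(self):
        t = _cohort_from_counts({("a", "x"): 2, ("b", "x"): 3,
                                 ("a", "y"): 3, ("b", "y"): 2})
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        assert select_test(spec, t).test_name == "fisher_exact"

    def test_non_normal_two_groups_use_mwu(self):
        rng = np.random.default_rng(3)
        n = 60
        df = pd.DataFrame({
            "id": [f"s{i}" for i in range(2 * n)],
            "group": ["x"] * n + ["y"] * n,
            "feat": pd.Series(
                np.concatenate([rng.exponential(1.0, n),
                                rng.exponential(1.5, n)]),
                dtype=object),
        })
        t = validate_roles(CohortTable(df=df), "group", "id")
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        res = select_test(spec, t)
        assert res.test_name == "mann_whitney_u"
        assert res.normality_p is not None and res.normality_p < 0.05

    def test_normal_three_groups_use_anova(self):
        rng = np.random.default_rng(3)
        n = 40
        df = pd.DataFrame({
            "id": [f"s{i}" for i in range(3 * n)],
            "group": ["x"] * n + ["y"] * n + ["z"] * n,
            "feat": pd.Series(rng.normal(10.0, 2.0, 3 * n), dtype=object),
        })
        t = validate_roles(CohortTable(df=df), "group", "id")
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        assert select_test(spec, t).test_name == "anova"

    def test_constant_feature_rejected(self):
        t = _cohort_from_counts({("only", "x"): 5, ("only", "y"): 5})
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        with pytest.raises(DegenerateSampleError):
            select_test(spec, t)

    def test_dispatch_is_deterministic(self):
        t = _cohort_from_counts({("f", "x"): 30, ("m", "x"): 20,
                                 ("f", "y"): 25, ("m", "y"): 25})
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        r1, r2 = select_test(spec, t), select_test(spec, t)
        assert r1 == r2


class TestDescribe:
    def test_proportions_match_published_gender_split(self):
        t = _cohort_from_counts({("Female", "covid"): 44, ("Male", "covid"): 68,
                                 ("Female", "ctrl"): 40, ("Male", "ctrl"): 63})
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        d = describe(spec, t)
        by_cat = {cat: prop for cat, _, prop in d.per_group["covid"]}
        assert round(by_cat["Female"], 2) == 0.39
        assert sum(p for _, _, p in d.per_group["covid"]) == pytest.approx(1.0)

    def test_quartiles_linear_interpolation(self):
        df = pd.DataFrame({
            "id": [f"s{i}" for i in range(10)],
            "group": ["x"] * 5 + ["y"] * 5,
            "v": pd.Series([1.0, 2, 3, 4, 5, 1.0, 2, 3, 4, 5], dtype=object),
        })
        t = validate_roles(CohortTable(df=df), "group", "id")
        spec = [s for s in infer_variable_types(t, {"v": "continuous"})
                if s.name == "v"][0]
        d = describe(spec, t)
        assert d.per_group["x"] == {
            "median": 3.0, "p25": 2.0, "p75": 4.0, "iqr_width": 2.0, "n": 5
        }

    def test_single_category_proportion_one(self):
        t = _cohort_from_counts({("only", "x"): 4, ("only", "y"): 6})
        spec = [s for s in infer_variable_types(t) if s.name == "feat"][0]
        d = describe(spec, t)
        assert d.per_group["x"] == [("only", 4, 1.0)]


class TestPValueFormatting:
    @pytest.mark.parametrize("p,text", [
        (0.7451, "0.745"), (1.0, "1.000"), (0.0004, "<0.001"), (0.05, "0.050"),
    ])
    def test_display_rule(self, p, text):
        assert format_p(p) == text


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(200, 600), st.integers(200, 600), st.integers(200, 600),
       st.integers(200, 600))
def test_chi_square_and_fisher_agree_asymptotically(a, b, c, d):
    """The continuity-corrected chi-square p converges to the Fisher exact p:
    with large cell counts the two differ by less than 0.05 absolute.  (The
    Yates correction keeps a visible gap at moderate counts — up to ~0.14 in
    the mid-p range for expected counts near 20 — so agreement is asserted
    where the asymptotics have actually set in.)"""
    ct = ContingencyTable(("r1", "r2"), ("c1", "c2"), np.array([[a, b], [c, d]]))
    assert abs(chi_square_test(ct).p_value - fisher_exact(ct).p_value) < 0.05
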