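"""Seeded post-hoc equalization of target-variable subpopulations.

Three algorithms, all operating by removing whole samples and never by
editing cells:

``samples``
    Uniform random downsampling of every subpopulation to the size of the
    smallest one — automated simple random sampling.
``proportions``
    Greedy iterative removal of the single sample whose deletion most reduces
    the total imbalance (impact) of the configured variables, stopping once
    no removal helps or the iteration budget is spent (optionally earlier,
    as soon as every configured variable's between-group test is
    non-significant).  Subpopulation relative size ordering is preserved.
``advanced``
    The hybrid: compute per-variable impact scores, process variables in
    descending impact order, and repeatedly remove from over-sized
    subpopulations the sample that best moves the current variable's
    proportions toward the pooled ones, until every subpopulation reaches the
    target size (the smallest subpopulation's size).  A MinThreshold floor
    protects small subpopulations from further reduction.

The imbalance measure ("impact score") of a variable is the total variation
distance between each subpopulation's category distribution and the pooled
distribution, summed over subpopulations.  Continuous variables enter via
quartile binning on the pooled distribution.  All randomness (tie-breaking,
downsampling) flows from one seeded generator over lexicographically sorted
identifiers, so identical inputs and seeds give identical outputs on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset_io import CohortTable, infer_variable_types
from .errors import (
    ConfigError,
    DegenerateSampleError,
    ProtectedIdError,
    ThresholdError,
    UnknownColumnError,
)
from .stats_engine import DescriptiveSummary, TestResult, describe, select_test

N_QUARTILE_BINS = 4  # continuous variables are pooled-quartile binned


@dataclass(frozen=True)
class EqualizeConfig:
    method: str  # "samples" | "proportions" | "advanced"
    bypass: bool = False
    variables: tuple = ()
    min_threshold: int = 5
    seed: int = 1
    protected_ids: frozenset = frozenset()
    alpha: float = 0.05
    max_iterations: int | None = None  # default: 10 x table size
    #: stop the greedy proportion balancer as soon as every configured
    #: variable tests non-significant (p > alpha), instead of running on to
    #: the impact minimum.  Saves samples but can leave a visible residual
    #: imbalance on small cohorts, where significance vanishes early.
    stop_on_nonsignificance: bool = False

    def validate(self, table: CohortTable) -> None:
        if self.method not in {"samples", "proportions", "advanced"}:
            raise ConfigError(f"unknown method {self.method!r}")
        if self.seed < 1:
            raise ConfigError("seed must be >= 1")
        if self.method in {"proportions", "advanced"} and not self.variables:
            raise ConfigError(f"method {self.method!r} requires variables")
        for v in self.variables:
            if v not in table.df.columns:
                raise UnknownColumnError(f"variable {v!r} not in table")
        if self.min_threshold < 0:
            raise ConfigError("min_threshold must be >= 0")
        present = set(map(str, table.ids()))
        unknown = {p for p in self.protected_ids if str(p) not in present}
        if unknown:
            raise ProtectedIdError(
                f"protected id(s) not in table: {sorted(map(str, unknown))}"
            )


@dataclass
class EqualizeResult:
    kept_ids: set
    removed_ids: set
    target_size: int
    impact_scores: dict  # variable -> score, descending
    iterations_run: int
    before_summary: dict  # variable -> (DescriptiveSummary, TestResult | None)
    after_summary: dict
    size_trace: list  # per-iteration {group: size}
    impact_trace: list  # total impact after each accepted removal
    flags: tuple = ()


def sanity_check(original_ids: set, result: EqualizeResult) -> bool:
    """True iff kept and removed ids partition the original identifiers."""
    original = set(original_ids)
    if result.kept_ids & result.removed_ids:
        return False
    return (result.kept_ids | result.removed_ids) == original


# ---------------------------------------------------------------------------
# impact scores


def _bin_codes(table: CohortTable, variables) -> tuple[dict, dict]:
    """Integer category codes per configured variable (rows of the table).

    Categorical values are factorized over lexicographically sorted
    categories; continuous values are binned at the pooled quartiles
    (computed once, on the full table).  Missing cells get their own code.
    """
    specs = {s.name: s for s in infer_variable_types(table)}
    codes: dict = {}
    n_cats: dict = {}
    for v in variables:
        col = table.df[v]
        spec = specs[v]
        if spec.kind == "categorical":
            cats = sorted(pd.unique(col.dropna()), key=str)
            lookup = {c: i for i, c in enumerate(cats)}
            arr = np.array(
                [len(cats) if pd.isna(x) else lookup[x] for x in col], dtype=int
            )
            n = len(cats) + int(col.isna().any())
        else:
            values = col.dropna().astype(float).to_numpy()
            qs = np.percentile(values, [25, 50, 75])
            arr = np.array(
                [
                    N_QUARTILE_BINS if pd.isna(x)
                    else int(np.searchsorted(qs, float(x), side="right"))
                    for x in col
                ],
                dtype=int,
            )
            n = N_QUARTILE_BINS + int(col.isna().any())
        codes[v] = arr
        n_cats[v] = n
    return codes, n_cats


def _impact_from_counts(counts: np.ndarray, sizes: np.ndarray) -> float:
    """Summed total variation distance of group distributions from pooled.

    ``counts`` is (groups x categories); ``sizes`` the group totals.
    """
    total = counts.sum()
    if total == 0:
        return 0.0
    pooled = counts.sum(axis=0) / total
    score = 0.0
    for g in range(counts.shape[0]):
        if sizes[g] == 0:
            continue
        score += 0.5 * np.abs(counts[g] / sizes[g] - pooled).sum()
    return float(score)


def compute_impact_scores(
    table: CohortTable, variables, target: str | None = None
) -> dict:
    """Impact score per variable, as a dict sorted by descending score."""
    if target is not None and target != table.target_column:
        table = replace(table, target_column=target)
    if table.target_column is None:
        raise ConfigError("table has no target role assigned")
    for v in variables:
        if v not in table.df.columns:
            raise UnknownColumnError(f"variable {v!r} not in table")
    codes, n_cats = _bin_codes(table, variables)
    groups = sorted(pd.unique(table.df[table.target_column].dropna()), key=str)
    gindex = {g: i for i, g in enumerate(groups)}
    garr = np.array([gindex[x] for x in table.df[table.target_column]], dtype=int)
    sizes = np.bincount(garr, minlength=len(groups))
    scores = {}
    for v in variables:
        counts = np.zeros((len(groups), n_cats[v]))
        np.add.at(counts, (garr, codes[v]), 1.0)
        scores[v] = _impact_from_counts(counts, sizes)
    return dict(sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])))


# ---------------------------------------------------------------------------
# the working state shared by the greedy algorithms


class _State:
    """Mutable removal state with O(groups x categories) impact deltas."""

    def __init__(self, table: CohortTable, config: EqualizeConfig):
        self.table = table
        self.config = config
        df = table.df
        self.ids = list(df[table.id_column])
        self.n = len(self.ids)
        self.groups = sorted(pd.unique(df[table.target_column].dropna()), key=str)
        gindex = {g: i for i, g in enumerate(self.groups)}
        self.garr = np.array([gindex[x] for x in df[table.target_column]], dtype=int)
        self.kept = np.ones(self.n, dtype=bool)
        self.sizes = np.bincount(self.garr, minlength=len(self.groups)).astype(int)
        self.initial_sizes = self.sizes.copy()
        self.protected = np.array(
            [str(i) in {str(p) for p in config.protected_ids} for i in self.ids]
        )
        self.codes, n_cats = _bin_codes(table, config.variables)
        self.counts = {}
        for v in config.variables:
            c = np.zeros((len(self.groups), n_cats[v]))
            np.add.at(c, (self.garr, self.codes[v]), 1.0)
            self.counts[v] = c
        # deterministic candidate ordering: row indices sorted by str(id)
        self.order = sorted(range(self.n), key=lambda i: str(self.ids[i]))
        self.rng = np.random.default_rng(config.seed)
        self.impact_trace: list[float] = []
        self.size_trace: list[dict] = []

    # -- impact bookkeeping -------------------------------------------------

    def total_impact(self) -> float:
        return sum(
            _impact_from_counts(self.counts[v], self.sizes)
            for v in self.config.variables
        )

    def variable_impact(self, v: str) -> float:
        return _impact_from_counts(self.counts[v], self.sizes)

    def impact_if_removed(self, row: int, variables=None) -> float:
        """Total impact over ``variables`` after hypothetically removing a row."""
        variables = variables if variables is not None else self.config.variables
        g = self.garr[row]
        sizes = self.sizes.copy()
        sizes[g] -= 1
        score = 0.0
        for v in variables:
            c = self.counts[v].copy()
            c[g, self.codes[v][row]] -= 1.0
            score += _impact_from_counts(c, sizes)
        return score

    def remove(self, row: int) -> None:
        g = self.garr[row]
        self.kept[row] = False
        self.sizes[g] -= 1
        for v in self.config.variables:
            self.counts[v][g, self.codes[v][row]] -= 1.0
        self.impact_trace.append(self.total_impact())
        self.size_trace.append(self.sizes_by_group())

    # -- views ----------------------------------------------------------------

    def sizes_by_group(self) -> dict:
        return {g: int(self.sizes[i]) for i, g in enumerate(self.groups)}

    def current_table(self) -> CohortTable:
        return replace(
            self.table, df=self.table.df[self.kept].reset_index(drop=True)
        )

    def kept_removed(self) -> tuple[set, set]:
        kept = {self.ids[i] for i in range(self.n) if self.kept[i]}
        removed = {self.ids[i] for i in range(self.n) if not self.kept[i]}
        return kept, removed

    def pick(self, rows: list[int]) -> int:
        """Seeded choice among tied candidates (rows already id-sorted)."""
        if len(rows) == 1:
            return rows[0]
        return rows[int(self.rng.integers(len(rows)))]

    def ordering_ok(self, row: int) -> bool:
        """Would removing ``row`` keep initial relative size ordering?"""
        g = self.garr[row]
        smaller = [
            i for i in range(len(self.groups))
            if self.initial_sizes[i] < self.initial_sizes[g]
        ]
        if not smaller:
            return True
        return self.sizes[g] - 1 >= max(self.sizes[i] for i in smaller)


def feature_summaries(table: CohortTable) -> dict:
    """Describe + test every feature variable; untestable ones get (desc, None)."""
    out = {}
    for spec in infer_variable_types(table):
        if spec.role != "feature":
            continue
        desc = describe(spec, table)
        try:
            res = select_test(spec, table)
        except DegenerateSampleError:
            res = None
        out[spec.name] = (desc, res)
    return out


def _finalize(state: _State, iterations: int, flags=()) -> EqualizeResult:
    kept, removed = state.kept_removed()
    scores = (
        compute_impact_scores(state.table, state.config.variables)
        if state.config.variables else {}
    )
    return EqualizeResult(
        kept_ids=kept,
        removed_ids=removed,
        target_size=int(state.initial_sizes.min()),
        impact_scores=scores,
        iterations_run=iterations,
        before_summary=feature_summaries(state.table),
        after_summary=feature_summaries(state.current_table()),
        size_trace=list(state.size_trace),
        impact_trace=list(state.impact_trace),
        flags=tuple(flags),
    )


def _max_iterations(config: EqualizeConfig, n_rows: int) -> int:
    return config.max_iterations if config.max_iterations is not None else 10 * n_rows


# ---------------------------------------------------------------------------
# the three algorithms


def equalize_samples(table: CohortTable, config: EqualizeConfig) -> EqualizeResult:
    """Downsample every subpopulation to the smallest subpopulation's size.

    Removal within a subpopulation is uniform over its unprotected samples.
    If a subpopulation's protected count exceeds the target size it ends
    larger, and the result is flagged.
    """
    config.validate(table)
    state = _State(table, config)
    target = int(state.initial_sizes.min())
    flags = []
    smallest = {
        i for i in range(len(state.groups))
        if state.initial_sizes[i] == state.initial_sizes.min()
    }
    removals = 0
    for gi, g in enumerate(state.groups):
        if not config.bypass and gi in smallest:
            continue
        excess = int(state.sizes[gi]) - target
        if excess <= 0:
            continue
        candidates = [
            r for r in state.order
            if state.garr[r] == gi and not state.protected[r]
        ]
        if len(candidates) < excess:
            flags.append(f"protected_exceeds_target:{g}")
            chosen = candidates
        else:
            idx = state.rng.choice(len(candidates), size=excess, replace=False)
            chosen = [candidates[i] for i in sorted(int(j) for j in idx)]
        for r in chosen:
            state.remove(r)
            removals += 1
    return _finalize(state, iterations=removals, flags=flags)


def _stop_all_nonsignificant(state: _State) -> bool:
    """True when every configured variable's between-group test has p > alpha."""
    current = state.current_table()
    specs = {s.name: s for s in infer_variable_types(current)}
    for v in state.config.variables:
        try:
            res = select_test(specs[v], current)
        except DegenerateSampleError:
            continue  # constant variable: trivially balanced
        if res.p_value <= state.config.alpha:
            return False
    return True


def equalize_proportions(table: CohortTable, config: EqualizeConfig) -> EqualizeResult:
    """Greedy single-sample removals that minimize total impact.

    Stops when no candidate removal strictly reduces total impact or at the
    iteration cap; with ``stop_on_nonsignificance`` set, also as soon as all
    configured variables test non-significant between groups.  With
    ``bypass=False`` the smallest subpopulation is exempt from removals.
    """
    config.validate(table)
    state = _State(table, config)
    limit = _max_iterations(config, state.n)
    smallest = {
        i for i in range(len(state.groups))
        if state.initial_sizes[i] == state.initial_sizes.min()
    }
    iterations = 0
    while iterations < limit:
        if config.stop_on_nonsignificance and _stop_all_nonsignificant(state):
            break
        current_total = state.total_impact()
        best_delta = 0.0
        best_rows: list[int] = []
        for r in state.order:
            if not state.kept[r] or state.protected[r]:
                continue
            gi = state.garr[r]
            if not config.bypass and gi in smallest:
                continue
            if state.sizes[gi] <= 1 or not state.ordering_ok(r):
                continue
            delta = state.impact_if_removed(r) - current_total
            if delta < best_delta - 1e-12:
                best_delta, best_rows = delta, [r]
            elif best_rows and abs(delta - best_delta) <= 1e-12:
                best_rows.append(r)
        if not best_rows:  # no removal strictly reduces total impact
            break
        state.remove(state.pick(best_rows))
        iterations += 1
    return _finalize(state, iterations=iterations)


def advanced_equalize(table: CohortTable, config: EqualizeConfig) -> EqualizeResult:
    """Hybrid size-and-proportion equalization.

    Impact scores are computed once and variables processed in descending
    impact order.  Each sweep removes, from every over-sized unprotected
    subpopulation and for the variable in hand, the sample whose removal
    best restores that variable's proportions (ties and near-ties resolved
    by total impact, then by the seeded generator).  Subpopulations at or
    below MinThreshold accept no further removals.  Terminates when all
    subpopulation sizes equal the target (smallest) size, no legal removal
    remains, or the sweep budget is exhausted.
    """
    config.validate(table)
    state = _State(table, config)
    target = int(state.initial_sizes.min())
    if config.min_threshold > target:
        raise ThresholdError(
            f"min_threshold={config.min_threshold} exceeds smallest "
            f"subpopulation size {target}"
        )
    scores = compute_impact_scores(table, config.variables)
    ordered_vars = list(scores)  # already descending
    limit = _max_iterations(config, state.n)
    sweeps = 0
    flags: list[str] = []
    while sweeps < limit and (state.sizes > target).any():
        progress = False
        for v in ordered_vars:
            for gi in range(len(state.groups)):
                if state.sizes[gi] <= target or state.sizes[gi] <= config.min_threshold:
                    continue
                best_key = None
                best_rows: list[int] = []
                for r in state.order:
                    if not state.kept[r] or state.protected[r]:
                        continue
                    if state.garr[r] != gi:
                        continue
                    key = (
                        state.impact_if_removed(r, variables=[v]),
                        state.impact_if_removed(r),
                    )
                    if best_key is None:
                        best_key, best_rows = key, [r]
                        continue
                    d0 = key[0] - best_key[0]
                    d1 = key[1] - best_key[1]
                    if d0 < -1e-12 or (abs(d0) <= 1e-12 and d1 < -1e-12):
                        best_key, best_rows = key, [r]
                    elif abs(d0) <= 1e-12 and abs(d1) <= 1e-12:
                        best_rows.append(r)
                if best_rows:
                    state.remove(state.pick(best_rows))
                    progress = True
        sweeps += 1
        if not progress:
            break
    if (state.sizes > target).any():
        flags.append("target_size_not_reached")
    result = _finalize(state, iterations=sweeps, flags=flags)
    result.impact_scores = scores
    return result
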