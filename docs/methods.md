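# Methods

This note documents the statistical model, the algorithms, and every
numerical choice in `cohortbalance`, in the package's own terms.

## Data model and assumptions

A cohort is a rectangular table with one **identifier** column (unique,
complete, never analyzed), one **target** column whose 2–15 distinct values
define the subpopulations, and feature columns. Cells are parsed to floats
only when they match a strict decimal literal (`.`-decimal, optional sign and
exponent); everything else is a string category; the tokens `""`, `na`,
`nan`, `n/a`, `null` (case-insensitive) are missing. CSV and XLSX inputs
parse to identical in-memory tables. A feature is **continuous** only when
every observed value is numeric *and* it has more than 15 distinct values;
otherwise it is categorical (15 is also the cap on target cardinality, so
small numeric codes behave as categories).

Assumptions: samples are exchangeable rows (no time structure, no repeated
measures); removal of whole samples is the only balancing operation;
missingness is treated as ignorable for imputation purposes and imputation
happens once, before any testing or balancing.

## Imputation

Per feature, skipping identifier and target:

- fraction missing ≥ 0.5 → no imputation, flagged `excess_missingness`;
- categorical → mode, ties broken by smallest string representation;
- continuous with < 3 observed values → median, flagged
  `normality_test_undefined` (Shapiro–Wilk needs n ≥ 3);
- continuous, Shapiro–Wilk p > 0.05 on the observed values → mean, else
  median.

Every action is logged (`ImputationRecord`) and surfaced in the report.

## Automated test selection

For a categorical feature, the feature × subpopulation contingency table is
built and:

- 2×2 with any expected count < 5 → Fisher's exact test (two-sided,
  hypergeometric sum);
- 2×2 otherwise → chi-square **with Yates continuity correction**;
- r×c → chi-square without correction; if > 20% of expected counts are < 5 a
  `low_expected_counts` warning is attached.

For a continuous feature, observed values are pooled and Shapiro–Wilk gates
the branch (p > 0.05 → parametric):

- 2 groups → Welch's t-test (unequal variances) or Mann–Whitney U;
- ≥ 3 groups → one-way ANOVA with Tukey HSD post hoc, or Kruskal–Wallis with
  Dunn's post hoc under Bonferroni correction.

The Mann–Whitney U uses the exact null distribution when min(n) ≤ 8 and the
pooled sample is tie-free, and the tie-corrected normal approximation
otherwise; the result records which was used. Dunn's test is implemented
directly (pairwise z on mean ranks with tie-corrected variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)), Bonferroni-multiplied p-values) because no
installed dependency provides it. Degenerate inputs follow fixed contracts:
all-identical samples yield statistic 0, p = 1 rather than an error.

Yates correction on 2×2 tables is a deliberate, verified choice: it
reproduces the published reference p-values this engine is validated against
(e.g. 0.745 on the 2×2 mortality table), which the uncorrected Pearson
statistic does not. A consequence worth knowing: corrected chi-square and
Fisher's exact can differ by up to ≈ 0.16 in p even when all expected counts
exceed 20; agreement within 0.05 is only reliable at cell counts in the
hundreds. Tests assert the behavior actually observed, not the folklore.

## Impact score

Let *q* be the pooled distribution of a variable's categories (continuous
variables are discretized into 4 bins at the pooled quartiles; missing values
form their own category). With *p_g* the distribution within subpopulation
*g*, the impact score is Σ_g TV(p_g, q), the summed total-variation
distances. It is 0 iff every subpopulation matches the pooled composition,
reaches 1.0 for two equal-sized perfectly separated groups, and is cheap to
update incrementally when one sample is removed — the greedy loops evaluate
"impact if this sample were removed" in O(groups × categories).

Quartile binning (4 bins) keeps per-bin counts large enough for stable
proportions at the cohort sizes this tool targets (tens to hundreds per
group) while still detecting location shifts.

## Equalization algorithms

Shared rules: a single `numpy.random.default_rng(seed)` drives all random
choices; removal candidates are processed in lexicographic identifier order
so same-seed runs are bit-reproducible; `protected_ids` are never removable;
by default the smallest subpopulation is exempt from removal unless
`bypass=True`; a removal is also illegal if it would drop a subpopulation's
size below the current size of any subpopulation that started out strictly
smaller (the initial relative size ordering is preserved). Every result
carries the kept/removed partition, size and impact traces, and must pass a
`sanity_check` (kept ∪ removed = input, kept ∩ removed = ∅) before a report
can be produced.

- **`samples`** — uniform random downsampling of each oversized
  subpopulation to the size of the smallest. If protections make the target
  unreachable, the subpopulation stops at its protected floor and the result
  is flagged.
- **`proportions`** — greedy: at each step, among all legal removals, take
  the one with the largest total-impact decrease (ties broken within 1e-12
  by the seeded rng); stop when no removal decreases total impact or an
  iteration cap (default 10 × table size) is hit.
- **`advanced`** — variables are ranked by impact score (descending); the
  target size is the smallest subpopulation's size; repeated sweeps remove,
  per variable and per oversized subpopulation, the candidate minimizing
  (that variable's impact, total impact) lexicographically with 1e-12
  epsilons, until all subpopulations reach the target. `min_threshold`
  (default 5) is a hard floor — configuring it above the smallest
  subpopulation raises `ThresholdError` up front. Forced size removals can
  perturb an already-balanced variable slightly, so total impact is not
  strictly monotone here; the contract is final total impact strictly below
  initial, and the full trace is exposed.

### Stopping rule (design choice)

An alternative stop for `proportions` — halt as soon as every configured
variable's selected test yields p > α — is available as
`stop_on_nonsignificance=True`, but is **not** the default. On small cohorts
the p-value crosses α while substantial imbalance remains (on a 50/50 cohort
with a 70%-vs-30% binary variable, the p-stop halts at a 0.23 proportion gap
with p = 0.063); running to the impact local minimum closes the gap to
< 0.1 and is what the documented postconditions guarantee. Non-significance
is a weak certificate of balance at small n, so the default optimizes the
effect size and reports the p-values rather than optimizing the p-values.

## Token-cost estimate

`estimate_tokens(rows, cols) = round_half_up(rows × (cols − 1) × 1.333)`.
One word is assumed per data cell; the identifier column is excluded because
it never reaches a language model; 1.333 is the literal constant from the
1000-tokens ≈ 750-words guideline (not 4/3 — the two differ in the seventh
significant digit and the reference values pin the literal). Verified
values: (26, 6) → 173, (225, 29) → 8398, (436, 3750) → 2,178,874.

## Synthetic generator

`SyntheticSpec` draws per-group exact-count cohorts: categorical variables
from per-group probability vectors, continuous variables from per-group
normal or lognormal (right-skewed) families, with uniform per-variable
missingness. It exists to exercise the pipeline — confounded vs balanced
categoricals, both branches of the normality gate, missingness — and makes
no claim of clinical realism (no correlations between features, no
informative missingness). The canonical fixture is 150 cases / 100 controls
with a 0.7-vs-0.3 binary confounder, a 0.5/0.5 balanced binary, a one-SD age
shift, and 5% missingness per feature.

## Verification

- Fisher's exact and the exact Mann–Whitney U are checked against
  independent combinatorial enumeration oracles (exact rational
  hypergeometric sums over all 2×2 tables with row margins ≤ 12;
  rank-arrangement enumeration for group sizes ≤ 6), not against another
  library call.
- t, F, and H statistics are checked against hand-coded closed forms.
- Property-based tests (hypothesis, derandomized) assert the partition and
  protection invariants across all three algorithms, seeds, and sizes.
- The acceptance suite (`tests/test_acceptance.py`) pins the published 2×2
  p-values at 3 d.p., the three token counts exactly, oracle equivalence,
  the equalization contracts (including a 20-seed median confounder gap
  < 0.05 via `proportions` with `bypass=True` — without bypass the smaller
  group is frozen and a one-sided removal schedule cannot close a
  0.7-vs-0.3 gap), and byte-identical CLI outputs across runs.

Problem sizes exercised: cohorts of 10–10,000 rows, 2–3 subpopulations in
depth (up to 15 for cardinality contracts), features up to a few thousand
columns only through the token estimator. Runtime on the 250-row fixture:
single equalization < 1 s; the full test suite ≈ 20 s.
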