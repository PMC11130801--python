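# cohortbalance

Post-hoc cohort equalization and automated statistical testing for tabular
case/control data.

## The problem

Observational biomedical datasets rarely arrive balanced. A cohort of 150
cases and 100 controls in which a binary covariate runs at 70% prevalence in
one subpopulation and 30% in the other will confound any downstream
comparison: differences attributed to case status may simply reflect the
covariate. When the study is already collected, the only lever left is
*post-hoc equalization* — removing whole samples so that the surviving
subpopulations match in size and/or covariate composition — followed by an
honest before/after statistical report.

`cohortbalance` implements that pipeline end to end:

- **Loading & typing** — CSV/XLSX ingestion with automatic inference of
  categorical vs continuous variables (a column is continuous only when it is
  all-numeric with more than 15 distinct values), a designated target
  (grouping) column with 2–15 subpopulations, and a unique identifier column.
- **Imputation** — mode for categorical variables; mean or median for
  continuous ones, chosen by a Shapiro–Wilk normality gate; variables with
  ≥ 50% missingness are left untouched and flagged.
- **Automated test selection** — chi-square with Yates continuity correction
  for 2×2 tables (Fisher's exact when any expected count < 5), r×c chi-square
  otherwise; Welch's t-test or Mann–Whitney U for two-group continuous
  comparisons and one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn–Bonferroni
  for more, dispatched by the same normality gate.
- **Three equalization algorithms** — plain downsampling to the smallest
  subpopulation (`samples`), greedy proportion balancing driven by an impact
  score (`proportions`), and a combined size-and-proportion procedure
  (`advanced`) with a `MinThreshold` floor, optional *bypass* of the
  smallest-subpopulation exemption, protected identifiers that are never
  removed, and full seeded determinism.
- **Reporting** — a plain-text audit report with descriptives, selected tests
  and p-values before and after, impact-score ranking, percentage changes, a
  kept/removed integrity check, and a projected LLM token cost for the table
  (one word per non-identifier cell × 1.333 tokens per word).
- **Synthetic data** — a seeded generator of confounded cohorts so the whole
  pipeline is testable without any external dataset.

### Impact score

For each variable *v*, samples are pooled across subpopulations and the
variable's categories (continuous variables are quartile-binned on the pooled
distribution) define a reference distribution *q*. The impact score is the
summed total-variation distance of each subpopulation's category distribution
*p_g* from the pooled one:

```
impact(v) = Σ_g  ½ Σ_c | p_g(c) − q(c) |
```

It is 0 when every subpopulation matches the pooled composition and grows
with confounding; it ranks variables for balancing priority and drives the
greedy removal step (each removal is chosen to maximize the impact decrease).

## Worked example

Generate the standard confounded fixture (150 cases / 100 controls, a binary
confounder at 0.7 vs 0.3 prevalence, a balanced binary variable, an
age shift, 5% missingness), impute, and balance the confounder:

```python
from cohortbalance import (
    EqualizeConfig, equalize_proportions, infer_variable_types,
    standard_confounded_fixture, select_test,
)
from cohortbalance.imputation import impute_table

table = standard_confounded_fixture(seed=1)
table, log = impute_table(table, infer_variable_types(table))
print("sizes before:", table.group_sizes())
for spec in infer_variable_types(table):
    if spec.role == "feature":
        r = select_test(spec, table)
        print(f"  {spec.name}: {r.test_name}  p={r.p_value:.3f}")

config = EqualizeConfig(
    method="proportions", variables=("confounder",), bypass=True, seed=1,
)
result = equalize_proportions(table, config)
after = table.subset_by_ids(result.kept_ids)
print("sizes after:", after.group_sizes())
print("removed:", len(result.removed_ids))
for spec in infer_variable_types(after):
    if spec.role == "feature":
        r = select_test(spec, after)
        print(f"  {spec.name}: {r.test_name}  p={r.p_value:.3f}")
```

Output (verbatim):

```
sizes before: {'case': 150, 'control': 100}
  confounder: chi_square  p=0.000
  balanced: chi_square  p=0.660
  age: t_test  p=0.000
sizes after: {'case': 149, 'control': 52}
removed: 49
  confounder: chi_square  p=1.000
  balanced: chi_square  p=0.865
  age: t_test  p=0.000
```

The confounder's prevalence gap closes to 0.732 vs 0.731 (p = 1.000) at the
cost of 49 removed controls, while the untargeted variables behave as
expected: `balanced` stays non-significant and `age` — deliberately left out
of `variables` — remains significant. Balancing is surgical, not magical:
only the configured variables are equalized.

The same pipeline is available from the shell:

```
cohortbalance simulate --seed 1 --out cohort.csv
cohortbalance equalize --input cohort.csv --target group --id id \
    --method advanced --variables confounder,balanced,age --seed 1 --out run/
cohortbalance tokens --rows 26 --cols 6   # prints 173
```

`equalize` writes `report.txt`, `kept.csv`, and `removed.csv`; identical
input, configuration, and seed give byte-identical output files.

## Testing

```
python -m pytest -q tests/
```

The suite covers dataset I/O, imputation, the statistics engine (including
independent combinatorial enumeration oracles for Fisher's exact test and the
exact Mann–Whitney U), all three equalization algorithms with property-based
invariants, reporting, the synthetic generator, and the CLI.
`tests/test_acceptance.py` holds one test per acceptance criterion.

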