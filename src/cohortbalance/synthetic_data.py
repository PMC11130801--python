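"""Seeded synthetic case/control cohorts with controllable imbalance.

Real clinical tables mix categorical variables whose prevalence differs
between groups (confounders), balanced nuisance variables, and continuous
measurements with group location shifts, all peppered with missing cells.
This module generates such tables deterministically from a seed so every
other module is testable without any external dataset.

Continuous variables come in two families — a bell-shaped (normal)
location-shift family and a right-skewed (lognormal) one — so both branches
of the normality gate in the test-selection tree are exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import MISSING, CohortTable, validate_roles
from .errors import ConfigError


@dataclass(frozen=True)
class CategoricalVar:
    """Per-group category probability vectors for one categorical variable."""

    name: str
    categories: tuple
    probs: dict  # group -> tuple of probabilities, same order as categories
    missing_rate: float = 0.0


@dataclass(frozen=True)
class ContinuousVar:
    """Per-group location/scale for one continuous variable."""

    name: str
    loc: dict  # group -> location
    scale: dict  # group -> scale
    family: str = "normal"  # "normal" | "lognormal"
    missing_rate: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    group_sizes: dict  # subpopulation label -> count
    categorical: tuple = ()
    continuous: tuple = ()
    seed: int = 1
    id_prefix: str = "S"
    target_name: str = "group"
    id_name: str = "id"

    def validate(self) -> None:
        if not 2 <= len(self.group_sizes) <= 15:
            raise ConfigError("group_sizes needs 2–15 subpopulations")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be positive")
        for var in self.categorical:
            for g in self.group_sizes:
                p = np.asarray(var.probs[g], dtype=float)
                if len(p) != len(var.categories):
                    raise ConfigError(
                        f"{var.name}: probability vector length mismatch for {g!r}"
                    )
                if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ConfigError(
                        f"{var.name}: probabilities for {g!r} must be a "
                        "non-negative vector summing to 1"
                    )


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw one cohort table from the spec, with roles already validated.

    Group counts are realized exactly (sampling is per group, not pooled);
    identifiers are sequential; missing cells are inserted uniformly at
    random per variable at its ``missing_rate``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.group_sizes)
    n_total = sum(spec.group_sizes.values())

    data: dict = {}
    data[spec.id_name] = [f"{spec.id_prefix}{i:04d}" for i in range(1, n_total + 1)]
    target = []
    for g in groups:
        target.extend([g] * spec.group_sizes[g])
    data[spec.target_name] = target

    for var in spec.categorical:
        col: list = []
        for g in groups:
            draws = rng.choice(
                len(var.categories), size=spec.group_sizes[g],
                p=np.asarray(var.probs[g], dtype=float),
            )
            col.extend(var.categories[int(d)] for d in draws)
        data[var.name] = _with_missing(col, var.missing_rate, rng)

    for var in spec.continuous:
        col = []
        for g in groups:
            n = spec.group_sizes[g]
            if var.family == "lognormal":
                draws = var.loc[g] + rng.lognormal(0.0, 1.0, size=n) * var.scale[g]
            else:
                draws = rng.normal(var.loc[g], var.scale[g], size=n)
            col.extend(float(x) for x in draws)
        data[var.name] = _with_missing(col, var.missing_rate, rng)

    df = pd.DataFrame({k: pd.Series(v, dtype=object) for k, v in data.items()})
    table = CohortTable(df=df)
    return validate_roles(table, target=spec.target_name, identifier=spec.id_name)


def _with_missing(col: list, rate: float, rng: np.random.Generator) -> list:
    if rate <= 0:
        return col
    mask = rng.random(len(col)) < rate
    return [MISSING if m else v for v, m in zip(col, mask)]


#: study conditions of the canonical confounded fixture
CONFOUNDED_GROUP_SIZES = {"case": 150, "control": 100}
CONFOUNDER_PREVALENCE = {"case": 0.7, "control": 0.3}
BALANCED_PREVALENCE = 0.5
CONTINUOUS_SHIFT_SD = 1.0  # case mean is one pooled SD above control
FIXTURE_MISSING_RATE = 0.05


def standard_confounded_fixture(seed: int = 1) -> CohortTable:
    """The canonical 250-sample two-group test cohort.

    Two subpopulations (150 cases, 100 controls); a binary confounder at
    0.7 vs 0.3 prevalence; a balanced binary variable at 0.5 in both groups;
    a continuous variable shifted by one pooled standard deviation between
    groups; 5% missingness on every feature.
    """
    spec = SyntheticSpec(
        group_sizes=dict(CONFOUNDED_GROUP_SIZES),
        categorical=(
            CategoricalVar(
                name="confounder",
                categories=("yes", "no"),
                probs={
                    "case": (CONFOUNDER_PREVALENCE["case"],
                             1 - CONFOUNDER_PREVALENCE["case"]),
                    "control": (CONFOUNDER_PREVALENCE["control"],
                                1 - CONFOUNDER_PREVALENCE["control"]),
                },
                missing_rate=FIXTURE_MISSING_RATE,
            ),
            CategoricalVar(
                name="balanced",
                categories=("yes", "no"),
                probs={
                    "case": (BALANCED_PREVALENCE, 1 - BALANCED_PREVALENCE),
                    "control": (BALANCED_PREVALENCE, 1 - BALANCED_PREVALENCE),
                },
                missing_rate=FIXTURE_MISSING_RATE,
            ),
        ),
        continuous=(
            ContinuousVar(
                name="age",
                loc={"case": 60.0 + CONTINUOUS_SHIFT_SD * 10.0, "control": 60.0},
                scale={"case": 10.0, "control": 10.0},
                missing_rate=FIXTURE_MISSING_RATE,
            ),
        ),
        seed=seed,
    )
    return generate_cohort(spec)
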