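import csv
from pathlib import Path

import pytest

from cohortbalance import (
    impute_table,
    infer_variable_types,
    standard_confounded_fixture,
)


@pytest.fixture
def write_csv(tmp_path):
    """Factory writing a list-of-rows table to a temp CSV and returning its path."""

    def _write(rows, name="table.csv"):
        path = tmp_path / name
        with open(path, "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        return path

    return _write


@pytest.fixture
def tiny_rows():
    """A 6-row cohort with two groups, a binary feature and a numeric feature."""
    return [
        ["id", "group", "sex", "age"],
        ["p1", "case", "F", "61.0"],
        ["p2", "case", "M", "58.5"],
        ["p3", "case", "F", "70.2"],
        ["p4", "control", "M", "66.1"],
        ["p5", "control", "F", "59.9"],
        ["p6", "control", "M", "63.3"],
    ]


@pytest.fixture(scope="session")
def confounded():
    """The canonical 250-sample confounded cohort (seed 1), raw."""
    return standard_confounded_fixture(seed=1)


@pytest.fixture(scope="session")
def confounded_imputed(confounded):
    """Same cohort after the standard typed imputation pass."""
    table, _ = impute_table(confounded, infer_variable_types(confounded))
    return table
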