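"""Before/after equalization reporting and LLM token-cost estimation.

The report is the tool's audit trail: dataset shape and variable typing,
quantified missingness and the imputation log, per-variable descriptive
statistics with the automatically selected test and its p-value before and
after equalization, the impact-score ranking, removed/surviving counts with
percentage changes, the kept/removed disjointness verdict, and a projected
token cost for feeding the table to an LLM assistant.

The token estimate deliberately avoids a real tokenizer: every data cell is
assumed to hold one word, the identifier column is excluded, and the OpenAI
guideline of 1000 tokens ≈ 750 words gives 1.333 tokens per word.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .dataset_io import CohortTable, VariableSpec
from .equalize import EqualizeResult, sanity_check
from .errors import ConfigError, ReportIntegrityError
from .imputation import ImputationRecord
from .stats_engine import format_p

TOKENS_PER_WORD = 1.333  # literal constant, not 4/3


def estimate_tokens(n_rows: int, n_columns: int) -> int:
    """Projected token count for a table: one word per non-identifier cell.

    ``round_half_up(n_rows * (n_columns - 1) * 1.333)`` — the identifier
    column never reaches the language model, so it is excluded.
    """
    if n_rows < 1 or n_columns < 2:
        raise ConfigError(
            "token estimate needs n_rows >= 1 and n_columns >= 2 "
            "(identifier plus at least one variable)"
        )
    words = n_rows * (n_columns - 1)
    return int(math.floor(words * TOKENS_PER_WORD + 0.5))


@dataclass
class Report:
    n_rows: int
    n_columns: int
    variable_specs: list
    missingness: list  # (variable, n_missing, fraction)
    imputation_log: list  # ImputationRecord
    before: dict  # variable -> (DescriptiveSummary, TestResult | None)
    after: dict | None
    impact_scores: dict
    group_sizes_before: dict
    group_sizes_after: dict | None
    surviving_count: int
    removed_count: int
    pct_changes: list  # (variable, group, category, before, after, pct, flag)
    sanity_ok: bool | None
    token_estimate: int
    processing_time: float | None = None
    timestamp: str | None = None

    def render(self) -> str:
        return render_report(self)


def build_report(
    before: CohortTable,
    result: EqualizeResult | None,
    specs: list,
    missingness: list,
    imputation_log: list | None = None,
    stats_before: dict | None = None,
    stats_after: dict | None = None,
    processing_time: float | None = None,
    timestamp: str | None = None,
) -> Report:
    """Assemble the structured report.

    With ``result=None`` (stats-only path) only the "before" block is
    produced.  With an equalization result, the kept/removed partition is
    sanity-checked first and a failure aborts report generation.
    """
    stats_before = stats_before if stats_before is not None else (
        result.before_summary if result is not None else {}
    )
    if result is not None:
        if not sanity_check(set(before.ids()), result):
            raise ReportIntegrityError(
                "kept and removed samples do not partition the input"
            )
        stats_after = stats_after if stats_after is not None else result.after_summary
        after_table = before.subset_by_ids(result.kept_ids)
        group_sizes_after = after_table.group_sizes()
        surviving, removed = len(result.kept_ids), len(result.removed_ids)
        sanity_ok = True
        impact = result.impact_scores
        pct = _pct_changes(stats_before, stats_after)
    else:
        stats_after, group_sizes_after = None, None
        surviving, removed = before.n_rows, 0
        sanity_ok, impact, pct = None, {}, []

    return Report(
        n_rows=before.n_rows,
        n_columns=before.n_columns,
        variable_specs=list(specs),
        missingness=list(missingness),
        imputation_log=list(imputation_log or []),
        before=dict(stats_before),
        after=dict(stats_after) if stats_after is not None else None,
        impact_scores=dict(impact),
        group_sizes_before=before.group_sizes(),
        group_sizes_after=group_sizes_after,
        surviving_count=surviving,
        removed_count=removed,
        pct_changes=pct,
        sanity_ok=sanity_ok,
        token_estimate=estimate_tokens(before.n_rows, before.n_columns),
        processing_time=processing_time,
        timestamp=timestamp,
    )


def _pct_changes(stats_before: dict, stats_after: dict) -> list:
    """Per-category count changes, as 100 x (after - before) / before."""
    out = []
    for var, (desc_b, _) in stats_before.items():
        if desc_b.kind != "categorical" or var not in stats_after:
            continue
        desc_a = stats_after[var][0]
        for group, entries_b in desc_b.per_group.items():
            after_counts = {
                cat: n for cat, n, _ in desc_a.per_group.get(group, [])
            }
            for cat, n_before, _ in entries_b:
                n_after = after_counts.get(cat, 0)
                if n_before == 0:
                    pct, flag = 0.0, "zero_baseline"
                else:
                    pct, flag = 100.0 * (n_after - n_before) / n_before, ""
                out.append((var, group, cat, n_before, n_after, pct, flag))
    return out


# ---------------------------------------------------------------------------
# rendering


def _hline(width: int = 78) -> str:
    return "-" * width


def _summary_lines(var: str, desc, test) -> list[str]:
    lines = [f"  Variable: {var} ({desc.kind})"]
    if desc.kind == "categorical":
        for group, entries in desc.per_group.items():
            parts = ", ".join(
                f"{cat}: {n} ({prop:.2f})" for cat, n, prop in entries
            )
            lines.append(f"    {group}: {parts}")
    else:
        for group, d in desc.per_group.items():
            lines.append(
                f"    {group}: median {d['median']:.6g} "
                f"(IQR {d['iqr_width']:.6g}; "
                f"p25 {d['p25']:.6g} - p75 {d['p75']:.6g}), n={d['n']}"
            )
    if test is not None:
        norm = (
            f", normality_p={format_p(test.normality_p)}"
            if test.normality_p is not None else ""
        )
        lines.append(
            f"    test={test.test_name} statistic={test.statistic:.6g} "
            f"p={format_p(test.p_value)}{norm}"
        )
        for (a, b), p in test.posthoc:
            lines.append(f"      posthoc {a} vs {b}: p={format_p(p)}")
    return lines


def render_report(report: Report) -> str:
    """Render the report to fixed-width UTF-8 plain text.

    Deterministic: two renders of the same report differ only in the
    timestamp line, which is omitted when no timestamp is set.
    """
    L: list[str] = []
    L.append("COHORT EQUALIZATION REPORT")
    L.append(_hline())
    if report.timestamp is not None:
        L.append(f"Generated: {report.timestamp}")
    L.append(f"Rows: {report.n_rows}")
    L.append(f"Columns: {report.n_columns}")
    L.append(f"Estimated tokens: {report.token_estimate}")
    if report.processing_time is not None:
        L.append(f"Processing time (s): {report.processing_time:.2f}")
    L.append("")
    L.append("VARIABLES")
    for s in report.variable_specs:
        L.append(
            f"  {s.name:<20} kind={s.kind:<12} role={s.role:<11} "
            f"missing={s.n_missing:<5} distinct={s.n_distinct:<5} "
            f"binary={'yes' if s.is_binary else 'no'}"
        )
    L.append("")
    L.append("MISSINGNESS")
    for name, n_missing, frac in report.missingness:
        L.append(f"  {name:<20} n_missing={n_missing:<5} fraction={frac:.4f}")
    if report.imputation_log:
        L.append("")
        L.append("IMPUTATION LOG")
        for rec in report.imputation_log:
            fill = "" if rec.fill_value is None else f" fill={rec.fill_value}"
            flag = f" [{rec.flag}]" if rec.flag else ""
            L.append(
                f"  {rec.variable:<20} method={rec.method:<7} "
                f"n_imputed={rec.n_imputed}{fill}{flag}"
            )
    L.append("")
    L.append("SUBPOPULATION SIZES (BEFORE)")
    for g, n in report.group_sizes_before.items():
        L.append(f"  {g}: {n}")
    L.append("")
    L.append("BEFORE EQUALIZATION")
    for var in report.before:
        desc, test = report.before[var]
        L.extend(_summary_lines(var, desc, test))

    if report.after is not None:
        L.append("")
        L.append("SUBPOPULATION SIZES (AFTER)")
        for g, n in report.group_sizes_after.items():
            L.append(f"  {g}: {n}")
        L.append("")
        L.append("AFTER EQUALIZATION")
        for var in report.after:
            desc, test = report.after[var]
            L.extend(_summary_lines(var, desc, test))
        L.append("")
        L.append("IMPACT SCORE RANKING")
        for var, score in report.impact_scores.items():
            L.append(f"  {var:<20} impact={score:.6f}")
        L.append("")
        L.append("PERCENTAGE CHANGES (category counts)")
        for var, group, cat, nb, na, pct, flag in report.pct_changes:
            suffix = f" [{flag}]" if flag else ""
            L.append(
                f"  {var:<16} {str(group):<10} {str(cat):<10} "
                f"before={nb:<5} after={na:<5} change={pct:+.1f}%{suffix}"
            )
        L.append("")
        L.append(f"Surviving samples: {report.surviving_count}")
        L.append(f"Removed samples: {report.removed_count}")
        verdict = "PASSED" if report.sanity_ok else "FAILED"
        L.append(f"Sanity check (kept/removed disjoint and exhaustive): {verdict}")
    else:
        L.append("")
        L.append(f"Surviving samples: {report.surviving_count}")
        L.append("Sanity check (kept/removed disjoint and exhaustive): "
                 "not applicable (no equalization performed)")
    L.append(_hline())
    return "\n".join(L) + "\n"


def save_report(report: Report, path: str | Path) -> Path:
    """Write the rendered report as a UTF-8 .txt file."""
    path = Path(path)
    if not path.parent.exists():
        raise ConfigError(f"directory does not exist: {path.parent}")
    path.write_text(render_report(report), encoding="utf-8")
    return path


def parse_report_tables(text: str) -> dict:
    """Back-parse the numeric content of a rendered report.

    Returns rows, columns, token estimate, surviving/removed counts, the
    per-variable p-values, group sizes and percentage changes — enough to
    verify a saved report against the structures that produced it.
    """
    out: dict = {"p_values": {}, "pct_changes": [], "group_sizes_before": {}}
    for m in re.finditer(r"^Rows: (\d+)$", text, re.M):
        out["n_rows"] = int(m.group(1))
    for m in re.finditer(r"^Columns: (\d+)$", text, re.M):
        out["n_columns"] = int(m.group(1))
    for m in re.finditer(r"^Estimated tokens: (\d+)$", text, re.M):
        out["token_estimate"] = int(m.group(1))
    for m in re.finditer(r"^Surviving samples: (\d+)$", text, re.M):
        out["surviving_count"] = int(m.group(1))
    for m in re.finditer(r"^Removed samples: (\d+)$", text, re.M):
        out["removed_count"] = int(m.group(1))
    before_block = text.split("BEFORE EQUALIZATION", 1)[-1]
    var = None
    for line in before_block.splitlines():
        vm = re.match(r"^  Variable: (\S+)", line)
        if vm:
            var = vm.group(1)
        tm = re.search(r"test=(\S+) statistic=\S+ p=(<?[\d.]+)", line)
        if tm and var is not None and var not in out["p_values"]:
            out["p_values"][var] = tm.group(2)
    sizes_block = re.search(
        r"SUBPOPULATION SIZES \(BEFORE\)\n((?:  .+\n)+)", text
    )
    if sizes_block:
        for line in sizes_block.group(1).splitlines():
            g, n = line.strip().rsplit(": ", 1)
            out["group_sizes_before"][g] = int(n)
    for m in re.finditer(
        r"^  (\S+)\s+(\S+)\s+(\S+)\s+before=(\d+)\s+after=(\d+)\s+"
        r"change=([+-][\d.]+)%", text, re.M,
    ):
        out["pct_changes"].append(
            (m.group(1), m.group(2), m.group(3),
             int(m.group(4)), int(m.group(5)), float(m.group(6)))
        )
    return out
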