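"""Human-readable rendering of assessment outputs.

The markdown report mirrors the tabular layout quality reviewers expect: one
section per check group (SACT records, LOT structure, mortality, follow-up),
one row per task with its value column, plus a baseline-characteristics
table and the quarterly initiation matrix as CSV.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .model import CohortBundle
from .qc import QCReport, TaskResult


def _fmt_value(t: TaskResult) -> str:
    if not t.applicable:
        return f"N/A ({t.omission_reason})"
    parts = []
    if t.numerator is not None and t.denominator is not None:
        pct = t.percent
        pct_s = "-" if pct is None else f"{pct:.1f}%"
        parts.append(f"{t.numerator}/{t.denominator} ({pct_s})")
    if t.stats:
        s = t.stats
        parts.append(
            f"median {s['median']} (IQR {s['q1']}-{s['q3']}; range {s['min']}-{s['max']}; "
            f"mean {s['mean']}, SD {s['sd']}; n={s['n']})"
        )
    return "; ".join(parts) if parts else "-"


def render_markdown(report: QCReport) -> str:
    """Render the 20-task report as a markdown document."""
    groups = [
        ("SACT administration and order records (tasks 1-9)", range(1, 10)),
        ("Line-of-therapy structure (tasks 10-14)", range(10, 15)),
        ("Mortality (tasks 15-17)", range(15, 18)),
        ("Follow-up (tasks 18-20)", range(18, 21)),
    ]
    lines: List[str] = [
        "# rwTTD data-quality assessment report",
        "",
        f"Config hash: `{report.config_hash[:16]}`",
        f"Target drug: {report.config['target_drug']['name']} "
        f"({report.config['target_route']})",
        f"Study window: {report.config['study_start_date']} to {report.config['data_cutoff_date']}",
        "",
    ]
    by_id = {t.task_id: t for t in report.tasks}
    for title, ids in groups:
        lines += [f"## {title}", "", "| Task | Dimension | Value |", "| --- | --- | --- |"]
        for i in ids:
            t = by_id[i]
            lines.append(f"| {i}. {t.title} | {t.dimension} | {_fmt_value(t)} |")
        lines.append("")
        for i in ids:
            t = by_id[i]
            if t.strata and t.applicable:
                lines.append(f"### Task {i} detail")
                lines.append("")
                lines.append("```")
                for key, value in t.strata.items():
                    lines.append(f"{key}: {value}")
                lines.append("```")
                lines.append("")
    if report.lot_comparison:
        lines += [
            "## Provided vs derived LOT tables (diagnostic)",
            "",
            f"{report.lot_comparison['patients_agreeing']} of "
            f"{report.lot_comparison['patients_compared']} patients agree exactly "
            f"(fraction {report.lot_comparison['agreement_fraction']}).",
            "",
        ]
    if report.degradation_log:
        lines += ["## Degradation log", ""]
        lines += [f"- {entry}" for entry in report.degradation_log]
        lines.append("")
    return "\n".join(lines)


def initiations_table(report: QCReport) -> pd.DataFrame:
    """Task 10 as a quarter x episode-group count matrix."""
    strata: Dict[str, Dict[str, int]] = report.task(10).strata or {}
    rows = [{"quarter": q, **counts} for q, counts in strata.items()]
    return pd.DataFrame(rows)


def demographics_table(bundle: CohortBundle) -> pd.DataFrame:
    """Baseline characteristics: sex, age, race, stage, index year."""
    n = len(bundle.patients)
    rows: List[Dict[str, object]] = []

    def add(characteristic: str, level: str, count: Optional[int], value: str = "") -> None:
        rows.append(
            {
                "characteristic": characteristic,
                "level": level,
                "n": "" if count is None else count,
                "percent": "" if count is None or not n else round(100.0 * count / n, 1),
                "value": value,
            }
        )

    for sex in ("female", "male", "unknown"):
        add("sex", sex, sum(1 for p in bundle.patients if p.sex == sex))
    ages = [p.age_at_index for p in bundle.patients if p.age_at_index is not None]
    if ages:
        arr = np.asarray(ages, dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])
        add(
            "age_at_index",
            "median (IQR)",
            None,
            f"{np.median(arr):.0f} ({q1:.0f}-{q3:.0f})",
        )
    bands = [("<18", 0, 17), ("18-44", 18, 44), ("45-64", 45, 64), ("65-88", 65, 88), (">=89", 89, 200)]
    for label, lo, hi in bands:
        add("age_band", label, sum(1 for a in ages if lo <= a <= hi))
    add("age_band", "missing", sum(1 for p in bundle.patients if p.age_at_index is None))
    races = sorted({p.race or "Missing" for p in bundle.patients})
    for race in races:
        add("race", race, sum(1 for p in bundle.patients if (p.race or "Missing") == race))
    for stage in ("0", "I", "II", "III", "IV", "unknown"):
        add("ajcc_stage", stage, sum(1 for p in bundle.patients if p.ajcc_stage == stage))
    years = sorted({p.index_date.year for p in bundle.patients})
    for year in years:
        add("index_year", str(year), sum(1 for p in bundle.patients if p.index_date.year == year))
    return pd.DataFrame(rows)
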