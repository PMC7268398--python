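"""Plain-text and markdown rendering of cost tables.

All numbers are formatted only here: AUD to 2 decimals, USD to whole
dollars, percentages to 1 decimal.  Steps that a project simply does
not perform render as ``n/a`` — distinct from a costed zero, which
renders as ``0.00`` / ``0.0%``.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .categories import step_order

__all__ = [
    "format_aud",
    "format_usd",
    "format_pct",
    "markdown_table",
    "frame_to_markdown",
    "render_results_summary",
]


def format_aud(value: float) -> str:
    return f"{value:,.2f}"


def format_usd(value: float) -> str:
    """Whole-dollar USD, half away from zero (as conventionally printed)."""
    return f"{math.floor(value + 0.5):,.0f}"


def format_pct(value: float) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    return f"{value:.1f}%"


def markdown_table(headers: Sequence[str], rows: Sequence[Sequence[str]],
                   align: Sequence[str] | None = None) -> str:
    """Minimal GitHub-style markdown table from pre-formatted cells."""
    if align is None:
        align = ["left"] + ["right"] * (len(headers) - 1)
    sep = {"left": ":--", "right": "--:", "center": ":-:"}
    lines = [
        "| " + " | ".join(str(h) for h in headers) + " |",
        "| " + " | ".join(sep.get(a, "---") for a in align) + " |",
    ]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def frame_to_markdown(frame: pd.DataFrame, formats: dict | None = None) -> str:
    """Render a DataFrame as markdown, applying per-column formatters."""
    formats = formats or {}
    headers = list(frame.columns)
    rows = []
    for _, record in frame.iterrows():
        cells = []
        for col in headers:
            value = record[col]
            fmt = formats.get(col)
            if fmt is not None:
                cells.append(fmt(value))
            elif isinstance(value, float):
                cells.append(f"{value:.4f}")
            else:
                cells.append(str(value))
        rows.append(cells)
    return markdown_table(headers, rows)


_STEP_TITLES = {
    "sampling": "1. Sampling",
    "dna_extraction": "2. DNA extraction",
    "library_preparation": "3. Library preparation",
    "sequencing": "4. Sequencing",
    "library_prep_and_sequencing": "3+4. Library preparation & sequencing",
    "analysis": "5. Analysis",
    "data_storage": "6. Data storage",
    "clinician_reporting": "7. Reporting to clinicians",
}


def step_title(key: str) -> str:
    return _STEP_TITLES.get(key, key)


def render_results_summary(results) -> str:
    """Text report for one project: items by step, shares, capital, totals."""
    project = results.project
    breakdown = results.breakdown
    rate = results.model.usd_per_aud
    width = 58

    lines = []
    title = project.display_name or project.name
    lines.append(f"Per-patient sequencing costs — {title}")
    lines.append(
        f"  patients: {project.n_patients}   technology: {project.technology}"
        f"   sample design: {project.sample_design}"
    )
    lines.append(f"  exchange rate: {rate} USD per AUD")
    lines.append("")

    items = results.step_table()
    for key in step_order(breakdown.merged):
        present = key in breakdown.present_steps
        if present:
            share = format_pct(breakdown.step_shares[key])
            lines.append(f"{step_title(key)}  [{share} of total]")
        else:
            lines.append(f"{step_title(key)}  [n/a]")
        if present:
            for _, row in items[items["step"] == key].iterrows():
                lines.append(
                    f"    - {row['label']:<40s} {format_aud(row['aud_per_patient']):>10s}"
                )
        else:
            lines.append("    (not performed)")
    lines.append("-" * width)
    lines.append(
        f"TOTAL per patient (excl. capital)   AU${format_aud(breakdown.total_excl_capital)}"
        f"  (US${format_usd(results.total_usd())})"
    )
    cap = breakdown.capital
    if cap is not None:
        lines.append(
            f"Capital: machine {format_aud(cap.machine_per_patient)}"
            f" + maintenance {format_aud(cap.maintenance_per_patient)}"
            f" = {format_aud(cap.capital_per_patient)}"
            f"  (+{format_pct(breakdown.capital_addon_percent)})"
        )
    lines.append(
        f"TOTAL per patient (incl. capital)   AU${format_aud(breakdown.total_incl_capital)}"
        f"  (US${format_usd(results.total_usd(include_capital=True))})"
    )
    lines.append("")
    lines.append("By cost type (incl. capital):")
    for _, row in results.type_table().iterrows():
        lines.append(
            f"    {row['cost_type']:<12s} {format_aud(row['aud_per_patient']):>10s}"
            f"   {format_pct(row['share_pct'])}"
        )
    return "\n".join(lines)
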