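"""Table rendering and figure-data export.

Results become pandas DataFrames with the row labels used in the
published tables, written as raw-numeric CSV and as Markdown with
``$1,234``-style currency formatting. The figure exporter emits a
long-format CSV (scenario, category, amount) ready for a stacked-bar
plot of remaining routine revenue versus telemedicine revenue at the
break-even and remote-monitoring rates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .clinic_model import BaseCaseResult, ClinicParameters
from .scenarios import (AugmentedYearResult, CapacityNeutralResult,
                        ScenarioComparison)
from .sensitivity import SensitivityRow

__all__ = ["base_case_table", "capacity_neutral_table", "augmented_table",
           "comparison_table", "sensitivity_table", "figure_data",
           "to_markdown", "write_tables"]

log = logging.getLogger("rpmecon")

_CURRENCY_ROWS = ("revenue", "salary", "rate", "cost", "gap", "margin")


def base_case_table(params: ClinicParameters,
                    result: BaseCaseResult) -> pd.DataFrame:
    rows = [
        ("Number of patients in practice", params.n_patients),
        ("Routine visits per patient per year",
         params.routine_visits_per_year),
        ("Reimbursement rate per routine visit", params.routine_rate),
        ("Marginal Reimbursement Revenue", result.marginal_revenue),
        ("Annual CDCES salary", params.cdces_salary),
        ("CDCES capacity (appointments per year)",
         result.annual_session_capacity),
        ("Total appointments needed (per year)", result.appointments_needed),
        ("FTE needed", result.fte_display),
        ("Total CDCES labor costs", result.labor_cost_display),
    ]
    return _frame(rows, "Base case")


def capacity_neutral_table(params: ClinicParameters,
                           result: CapacityNeutralResult) -> pd.DataFrame:
    rows = [
        ("In person visits per patient per year",
         result.remaining_visits_per_patient),
        ("Marginal Reimbursement Revenue", result.remaining_revenue),
        ("Revenue Gap", result.revenue_gap),
        ("Appointments repurposed for telehealth",
         result.repurposed_appointments),
        ("Duration of in-person visit (mins)", params.routine_minutes),
        ("Duration of telemedicine appointment (mins)", params.tele_minutes),
        ("Total telemedicine appointments freed up", result.freed_contacts),
        ("Minimum reimbursement rate per telemedicine appointment",
         "N/A" if result.break_even_rate is None else result.break_even_rate),
        ("RPM reimbursement rate", params.rpm_rate),
        ("Potential marginal RPM reimbursement revenue", result.rpm_revenue),
        ("Margin", result.margin),
    ]
    return _frame(rows, "Capacity-neutral scenario")


def augmented_table(params: ClinicParameters,
                    results: list[AugmentedYearResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        pct = f"{round_half_up(r.coverage * 100, 0):.0f}%"
        rows += [
            (f"Year {r.year_index}: Percentage of patients receiving "
             "telemedicine", pct),
            (f"Year {r.year_index}: Telemedicine appointments needed per "
             "year", r.contacts_needed),
            (f"Year {r.year_index}: CDCES capacity (appointments per year)",
             params.annual_session_capacity),
            (f"Year {r.year_index}: Additional FTE needed",
             r.additional_fte_display),
            (f"Year {r.year_index}: Additional marginal CDCES labor costs",
             r.additional_labor_display),
            (f"Year {r.year_index}: Minimum reimbursement rate per "
             "telemedicine appointment",
             "N/A" if r.break_even_rate is None else r.break_even_rate),
            (f"Year {r.year_index}: RPM reimbursement rate", params.rpm_rate),
            (f"Year {r.year_index}: Potential marginal RPM reimbursement "
             "revenue", r.rpm_revenue),
            (f"Year {r.year_index}: Margin", r.margin),
        ]
    return _frame(rows, "Augmented-capacity scenario")


def comparison_table(comparison: ScenarioComparison) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(comparison.rows, orient="index",
                                columns=list(comparison.columns))
    df.index.name = "Parameters"
    return df


def sensitivity_table(baseline: float,
                      rows: list[SensitivityRow]) -> pd.DataFrame:
    labels = [("Baseline", 1.0, baseline, False)]
    for r in rows:
        direction = "increase" if r.multiplier > 1 else "decrease"
        pct = round_half_up(abs(r.multiplier - 1) * 100, 0)
        labels.append((f"{pct:.0f}% {direction} in {r.parameter}",
                       r.multiplier, r.break_even_rate,
                       r.changed_from_baseline))
    df = pd.DataFrame(labels, columns=["Sensitivity Analysis", "Multiplier",
                                       "Minimum reimbursement rate",
                                       "Changed from baseline"])
    return df.set_index("Sensitivity Analysis")


def figure_data(neutral: CapacityNeutralResult,
                augmented: list[AugmentedYearResult]) -> pd.DataFrame:
    """Long-format stacked-bar data for the two adoption scenarios."""
    records = [("capacity-neutral", "remaining routine revenue",
                neutral.remaining_revenue),
               ("capacity-neutral", "telemedicine revenue at break-even",
                (neutral.break_even_rate or 0) * neutral.freed_contacts),
               ("capacity-neutral", "telemedicine revenue at RPM rate",
                neutral.rpm_revenue)]
    for r in augmented:
        label = f"augmented-year-{r.year_index}"
        records += [
            (label, "telemedicine revenue at break-even",
             (r.break_even_rate or 0) * r.contacts_needed),
            (label, "telemedicine revenue at RPM rate", r.rpm_revenue),
        ]
    return pd.DataFrame(records, columns=["scenario", "category", "amount"])


def _frame(rows: list[tuple], title: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=[title, "Value"])
    return df.set_index(title)


def _fmt_cell(label: str, column: str, value) -> str:
    if isinstance(value, str):
        return value
    if isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    text = f"{label} {column}".lower()
    if "multiplier" in column.lower() or "fte" in text:
        return f"{float(value):,.2f}"
    if any(w in text for w in _CURRENCY_ROWS):
        v = round_half_up(float(value), 2)
        # per-contact rates keep cents; annual totals print whole dollars
        if "rate" in text or v != int(v):
            return f"${v:,.2f}"
        return f"${int(v):,}"
    v = float(value)
    return f"{v:,.2f}" if v != int(v) else f"{int(v):,}"


def to_markdown(df: pd.DataFrame) -> str:
    """Render a results DataFrame as a Markdown pipe table.

    Currency rows/columns (revenue/cost/rate/gap/margin labels) get a
    leading $ and thousands separators — cents for per-contact rates,
    whole dollars for annual totals; everything else prints as a plain
    number and booleans as yes/no.
    """
    header = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    for label, row in df.iterrows():
        cells = [_fmt_cell(str(label), str(col), v)
                 for col, v in row.items()]
        lines.append("| " + " | ".join([str(label)] + cells) + " |")
    return "\n".join(lines) + "\n"


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path,
                 formats: tuple[str, ...] = ("csv", "md")) -> list[Path]:
    """Write each named table in the requested formats; return the paths."""
    if not tables:
        log.warning("no tables to write; nothing done")
        return []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if "csv" in formats:
            p = outdir / f"{name}.csv"
            df.to_csv(p)
            written.append(p)
        if "md" in formats:
            p = outdir / f"{name}.md"
            p.write_text(to_markdown(df))
            written.append(p)
    return written
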