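"""One-way sensitivity analysis on the break-even reimbursement rate.

Each analysis scales a single parameter by a multiplier (default 0.5 and
1.5), re-runs the chosen adoption scenario, and records the resulting
minimum per-contact reimbursement rate. The break-even rate responds only
to a handful of parameters — in the capacity-neutral scenario, the routine
reimbursement rate, the visit durations, and the HbA1c outcome value; in
the augmented scenario, the CDCES salary, the CDCES capacity, the
durations, and the outcome value — and the analysis makes those
(in)sensitivities explicit.

Two perturbation names are virtual: ``cdces_capacity`` scales the annual
session capacity as a whole (through its weeks-per-year factor) and
``coverage`` scales every per-year coverage fraction, clamped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clinic_model import ClinicParameters
from .scenarios import run_augmented_capacity, run_capacity_neutral

__all__ = ["SensitivityRow", "PERTURBABLE", "perturb", "one_way_sensitivity",
           "scenario_break_even"]

SCENARIOS = ("capacity-neutral", "augmented")

#: direct ClinicParameters fields that may be perturbed, plus virtual names
PERTURBABLE = (
    "n_patients", "routine_visits_per_year", "routine_rate", "cdces_salary",
    "routine_minutes", "tele_minutes", "rpm_rate",
    "repurposed_visits_per_patient", "hba1c_value_per_patient",
    "cdces_capacity", "coverage",
)


@dataclass(frozen=True)
class SensitivityRow:
    """Break-even rate after scaling one parameter by one multiplier."""

    scenario: str
    parameter: str
    multiplier: float
    break_even_rate: float
    changed_from_baseline: bool


def perturb(params: ClinicParameters, parameter: str,
            multiplier: float) -> ClinicParameters:
    """Return a copy of ``params`` with one parameter scaled.

    Raises
    ------
    KeyError
        If ``parameter`` is not a recognised perturbable name.
    """
    if parameter not in PERTURBABLE:
        raise KeyError(
            f"unknown parameter {parameter!r}; choose one of {PERTURBABLE}")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if parameter == "cdces_capacity":
        return params.replace(weeks_per_year=params.weeks_per_year
                              * multiplier)
    if parameter == "coverage":
        return params.replace(coverage_by_year=tuple(
            min(1.0, c * multiplier) for c in params.coverage_by_year))
    return params.replace(**{parameter: getattr(params, parameter)
                             * multiplier})


def scenario_break_even(params: ClinicParameters, scenario: str) -> float:
    """Break-even rate of one scenario (year 1 for augmented)."""
    if scenario == "capacity-neutral":
        return run_capacity_neutral(params).break_even_rate
    if scenario == "augmented":
        return run_augmented_capacity(params)[0].break_even_rate
    raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")


def one_way_sensitivity(params: ClinicParameters, scenario: str,
                        parameters: list[str],
                        multipliers: list[float] = (1.5, 0.5),
                        ) -> list[SensitivityRow]:
    """Re-run ``scenario`` once per (parameter, multiplier) pair."""
    baseline = scenario_break_even(params, scenario)
    rows = []
    for parameter in parameters:
        for multiplier in multipliers:
            rate = scenario_break_even(perturb(params, parameter, multiplier),
                                       scenario)
            rows.append(SensitivityRow(
                scenario=scenario, parameter=parameter,
                multiplier=multiplier, break_even_rate=rate,
                changed_from_baseline=rate != baseline))
    return rows
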