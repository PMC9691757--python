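"""Adoption scenarios, break-even reimbursement and margins.

Two pathways to algorithm-enabled remote patient monitoring are modelled
against the status-quo base case:

* **capacity-neutral** — the clinic repurposes some routine education
  visits as flexible message-based telemedicine contacts. Education
  revenue drops (the *revenue gap*); CDCES labor cost is unchanged. Each
  repurposed 30-minute session accommodates ``floor(d_r / d_t)`` contacts
  (six at the defaults).
* **augmented-capacity** — the clinic keeps all routine visits and hires
  additional fractional CDCES capacity to cover a target share of the
  population with one contact per review period (75% in year 1, 50% in
  year 2 by default). The added dollar-rounded labor cost plays the role
  of the revenue gap.

In either case the *break-even rate* is the minimum per-contact
reimbursement making the clinic's net margin change versus the base case
non-negative. A clinic may also credit a per-patient dollar value for the
0.5% HbA1c improvement associated with the program; that value is
subtracted from the gap (floored at zero) before solving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from ._rounding import round_half_up
from .clinic_model import ClinicParameters, InvalidParameterError, \
    build_base_case, education_revenue

__all__ = [
    "CapacityNeutralResult", "AugmentedYearResult", "ScenarioComparison",
    "NoContactsError", "BreakEvenNotFoundError",
    "freed_contacts", "revenue_gap", "apply_outcome_offset",
    "break_even_rate", "break_even_rate_brute_force", "contacts_needed",
    "telemedicine_capacity", "run_capacity_neutral", "run_augmented_capacity",
    "compare_scenarios",
]


class NoContactsError(ValueError):
    """Break-even per contact is undefined when no contacts are delivered."""


class BreakEvenNotFoundError(ValueError):
    """The brute-force scan found no break-even below its upper bound."""


@dataclass(frozen=True)
class CapacityNeutralResult:
    """Capacity-neutral scenario outputs (annual, USD).

    ``revenue_gap`` is net of any HbA1c outcome offset and floored at
    zero. ``break_even_rate`` is ``None`` when nothing is repurposed.
    """

    remaining_visits_per_patient: float
    remaining_revenue: float
    revenue_gap: float
    repurposed_appointments: float
    freed_contacts: float
    break_even_rate: Optional[float]
    rpm_revenue: float
    margin: float


@dataclass(frozen=True)
class AugmentedYearResult:
    """One program year of the augmented-capacity scenario.

    ``additional_labor_cost`` is unrounded; ``additional_labor_display``
    is the dollar-rounded figure that margins and break-even rates are
    computed from, matching the published tables.
    """

    year_index: int
    coverage: float
    contacts_needed: float
    telemedicine_capacity: float
    additional_fte: float
    additional_labor_cost: float
    break_even_rate: Optional[float]
    rpm_revenue: float
    margin: float

    @property
    def additional_fte_display(self) -> float:
        return round_half_up(self.additional_fte, 2)

    @property
    def additional_labor_display(self) -> float:
        return round_half_up(self.additional_labor_cost, 0)


@dataclass(frozen=True)
class ScenarioComparison:
    """Aligned base-case / capacity-neutral / augmented-year-1 columns.

    ``rows`` maps a row label to a 3-tuple of cell values; cells that do
    not apply to a scenario hold the string ``"N/A"``.
    """

    rows: dict

    columns = ("Base case", "Capacity-neutral", "Augmented-capacity")


def freed_contacts(repurposed_appointments: float, routine_minutes: float,
                   tele_minutes: float) -> float:
    """Telemedicine contacts the repurposed sessions can accommodate.

    Each repurposed routine session holds ``floor(routine/tele)`` whole
    contacts ("up to six" at 30 vs 5 minutes); partial contacts are not
    carried across sessions.
    """
    if tele_minutes <= 0:
        raise InvalidParameterError("tele_minutes must be > 0")
    return repurposed_appointments * int(routine_minutes // tele_minutes)


def revenue_gap(repurposed_appointments: float, routine_rate: float) -> float:
    """Education revenue lost by repurposing routine appointments."""
    return repurposed_appointments * routine_rate


def apply_outcome_offset(gap: float, hba1c_value_per_patient: float,
                         n_patients: float) -> float:
    """Reduce the gap by the population-wide HbA1c value, floored at zero."""
    return max(0.0, gap - hba1c_value_per_patient * n_patients)


def break_even_rate(net_gap: float, contacts: float) -> float:
    """Minimum per-contact reimbursement closing ``net_gap``, in cents.

    Raises
    ------
    NoContactsError
        If ``contacts`` is zero — a per-contact rate is then undefined.
    """
    if contacts <= 0:
        raise NoContactsError("break-even rate undefined with no contacts")
    return round_half_up(net_gap / contacts, 2)


def break_even_rate_brute_force(
        scenario_evaluator: Callable[[float], float],
        step: float = 0.01, upper_bound: float = 100.0) -> float:
    """Cent-grid break-even found by scanning, independent of closed forms.

    Walks the cent grid from zero until the net margin change versus the
    base case turns non-negative, then returns the grid point nearer the
    zero crossing (ties resolve upward). That grid point is the half-up
    cent rounding of the exact break-even, so the scan reproduces the
    published per-contact rates. ``scenario_evaluator`` must be monotone
    nondecreasing in the rate.
    """
    n_steps = int(round(upper_bound / step))
    prev = scenario_evaluator(0.0)
    if prev >= 0:
        return 0.0
    for i in range(1, n_steps + 1):
        rate = i * step  # cent grid; i*0.01 is exact enough at this scale
        cur = scenario_evaluator(rate)
        if cur >= 0:
            # crossing lies between the two grid points; pick the closer
            # (float-tolerant so exact half-cent ties resolve upward)
            tol = 1e-7 * (abs(cur) + abs(prev) + 1.0)
            closer = rate if cur <= -prev + tol else rate - step
            return round_half_up(closer, 2)
        prev = cur
    raise BreakEvenNotFoundError(
        f"no break-even rate found below {upper_bound}")


def contacts_needed(n_patients: float, coverage: float,
                    periods_per_year: int) -> float:
    """Annual contact demand covering ``coverage`` of patients per period.

    Per-period demand is rounded to the nearest whole patient before
    annualizing (75% of 100 patients monthly -> 900/year).
    """
    if not 0 <= coverage <= 1:
        raise InvalidParameterError("coverage must lie in [0, 1]")
    return round_half_up(n_patients * coverage, 0) * periods_per_year


def telemedicine_capacity(annual_session_capacity: float,
                          routine_minutes: float,
                          tele_minutes: float) -> float:
    """Annual telemedicine-contact capacity of one FTE.

    Converts session capacity at the floored duration ratio (1,300
    sessions -> 7,800 five-minute contacts). Duration changes affect only
    this conversion, never the session capacity itself.
    """
    if tele_minutes <= 0:
        raise InvalidParameterError("tele_minutes must be > 0")
    return annual_session_capacity * int(routine_minutes // tele_minutes)


def run_capacity_neutral(params: ClinicParameters) -> CapacityNeutralResult:
    """Evaluate the capacity-neutral scenario.

    Labor cost and total capacity are unchanged from the base case; the
    repurposed education revenue is the gap to recoup. With nothing
    repurposed the scenario degenerates to the base case and the
    break-even rate is not applicable (``None``).
    """
    repurposed = params.n_patients * params.repurposed_visits_per_patient
    remaining_visits = (params.routine_visits_per_year
                        - params.repurposed_visits_per_patient)
    gap = apply_outcome_offset(
        revenue_gap(repurposed, params.routine_rate),
        params.hba1c_value_per_patient, params.n_patients)
    freed = freed_contacts(repurposed, params.routine_minutes,
                           params.tele_minutes)
    rpm_revenue = freed * params.rpm_rate
    return CapacityNeutralResult(
        remaining_visits_per_patient=remaining_visits,
        remaining_revenue=education_revenue(
            params.n_patients, remaining_visits, params.routine_rate),
        revenue_gap=gap,
        repurposed_appointments=repurposed,
        freed_contacts=freed,
        break_even_rate=break_even_rate(gap, freed) if freed > 0 else None,
        rpm_revenue=rpm_revenue,
        margin=rpm_revenue - gap,
    )


def run_augmented_capacity(params: ClinicParameters
                           ) -> list[AugmentedYearResult]:
    """Evaluate the augmented-capacity scenario, one result per year.

    Margins subtract the dollar-rounded labor cost (the published
    convention); the break-even rate divides that rounded cost, net of
    any outcome offset, by the year's contact count.
    """
    if not params.coverage_by_year:
        raise InvalidParameterError("coverage_by_year must be nonempty")
    capacity = telemedicine_capacity(params.annual_session_capacity,
                                     params.routine_minutes,
                                     params.tele_minutes)
    results = []
    for year, coverage in enumerate(params.coverage_by_year, start=1):
        contacts = contacts_needed(params.n_patients, coverage,
                                   params.periods_per_year)
        fte = contacts / capacity
        labor = fte * params.cdces_salary
        labor_display = round_half_up(labor, 0)
        net_gap = apply_outcome_offset(labor_display,
                                       params.hba1c_value_per_patient,
                                       params.n_patients)
        rpm_revenue = contacts * params.rpm_rate
        results.append(AugmentedYearResult(
            year_index=year,
            coverage=coverage,
            contacts_needed=contacts,
            telemedicine_capacity=capacity,
            additional_fte=fte,
            additional_labor_cost=labor,
            break_even_rate=(break_even_rate(net_gap, contacts)
                             if contacts > 0 else None),
            rpm_revenue=rpm_revenue,
            margin=rpm_revenue - labor_display,
        ))
    return results


def compare_scenarios(params: ClinicParameters) -> ScenarioComparison:
    """Side-by-side base-case / capacity-neutral / augmented-year-1 table."""
    base = build_base_case(params)
    neutral = run_capacity_neutral(params)
    aug = run_augmented_capacity(params)[0] if params.coverage_by_year else None
    na = "N/A"

    def _be(x):
        return na if x is None else x

    rows = {
        "Routine visits per patient per year": (
            params.routine_visits_per_year,
            neutral.remaining_visits_per_patient,
            params.routine_visits_per_year),
        "Reimbursement rate per routine visit": (
            params.routine_rate,) * 3,
        "CDCES capacity (appointments per year)": (
            base.annual_session_capacity,) * 3,
        "Annual CDCES salary": (params.cdces_salary,) * 3,
        "Duration of in-person visit (mins)": (params.routine_minutes,) * 3,
        "Duration of telemedicine appointment (mins)": (
            params.tele_minutes,) * 3,
        "Routine appointments repurposed for telehealth": (
            na, neutral.repurposed_appointments, 0),
        "Lost revenue from routine appointments": (
            na, neutral.revenue_gap, 0),
        "Additional FTE needed": (
            na, 0, aug.additional_fte_display if aug else na),
        "Additional marginal CDCES labor costs": (
            na, 0, aug.additional_labor_display if aug else na),
        "Minimum reimbursement rate per telemedicine appointment": (
            na, _be(neutral.break_even_rate),
            _be(aug.break_even_rate) if aug else na),
    }
    return ScenarioComparison(rows=rows)
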