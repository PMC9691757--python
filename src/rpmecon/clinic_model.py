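"""Clinic parameters and the status-quo base case.

The model describes a pediatric type 1 diabetes clinic in which diabetes
education is delivered by Certified Diabetes Care and Education Specialists
(CDCES) at a fixed cadence and reimbursed fee-for-service. The base case
computes the clinic's marginal education revenue, the CDCES appointment
demand, the full-time-equivalent (FTE) staffing that demand implies, and
the resulting marginal labor cost.

All quantities are yearly marginal figures in plain USD; one-time fixed
costs (software, hardware, training) and revenue from non-CDCES staff are
outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

from ._rounding import round_half_up

__all__ = ["ClinicParameters", "BaseCaseResult", "InvalidParameterError",
           "annual_session_capacity", "education_revenue", "fte_required",
           "labor_cost", "build_base_case"]


class InvalidParameterError(ValueError):
    """A clinic parameter violates a model invariant."""


@dataclass(frozen=True)
class ClinicParameters:
    """Scalar inputs of the financial model.

    Defaults are the published reference values for a 100-patient cohort:
    quarterly education visits reimbursed at $56 (2022 Medicare national
    rate for 30-minute diabetes self-management training, CPT G0108), an
    $85,000 CDCES salary, a capacity of 5 sessions/day x 5 days/week x 52
    weeks, 30-minute routine visits versus 5-minute message-based
    telemedicine contacts, a $35 remote-monitoring rate (CGM analysis and
    interpretation, CPT 95251), one repurposed visit per patient in the
    capacity-neutral scenario, and 75%/50% per-period telemedicine coverage
    in years 1 and 2 of the augmented-capacity scenario.

    Parameters
    ----------
    n_patients
        Patients in the practice.
    routine_visits_per_year
        Routine CDCES education visits per patient per year.
    routine_rate
        Reimbursement per routine visit, USD.
    cdces_salary
        Annual salary of one full-time CDCES, USD.
    sessions_per_day, days_per_week, weeks_per_year
        Factors of one FTE's annual education-session capacity.
    routine_minutes, tele_minutes
        Durations of a routine visit and of a message-based telemedicine
        contact, minutes. Their floored ratio is the number of contacts one
        repurposed session can accommodate.
    rpm_rate
        Reimbursement per telemedicine contact under remote-patient-
        monitoring billing codes, USD.
    repurposed_visits_per_patient
        Routine visits per patient per year shifted to telemedicine in the
        capacity-neutral scenario.
    coverage_by_year
        Fraction of the population receiving a telemedicine contact per
        review period, one entry per program year (augmented scenario).
    periods_per_year
        Review periods per year in the financial model (monthly by
        default; the clinical program reviews weekly but bills monthly).
    hba1c_value_per_patient
        Dollar value per patient per year the clinic attributes to a 0.5%
        HbA1c improvement; subtracted from the revenue gap before solving
        for the break-even rate. Zero by default.
    """

    n_patients: float = 100
    routine_visits_per_year: float = 4
    routine_rate: float = 56.0
    cdces_salary: float = 85_000.0
    sessions_per_day: float = 5
    days_per_week: float = 5
    weeks_per_year: float = 52
    routine_minutes: float = 30.0
    tele_minutes: float = 5.0
    rpm_rate: float = 35.0
    repurposed_visits_per_patient: float = 1
    coverage_by_year: tuple[float, ...] = (0.75, 0.50)
    periods_per_year: int = 12
    hba1c_value_per_patient: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coverage_by_year",
                           tuple(self.coverage_by_year))
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "coverage_by_year":
                if any(not 0 <= c <= 1 for c in v):
                    raise InvalidParameterError(
                        f"coverage_by_year entries must lie in [0, 1]: {v}")
            elif v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        if self.tele_minutes <= 0:
            raise InvalidParameterError("tele_minutes must be > 0")
        if self.routine_minutes < self.tele_minutes:
            raise InvalidParameterError(
                "routine_minutes must be >= tele_minutes")
        if self.repurposed_visits_per_patient > self.routine_visits_per_year:
            raise InvalidParameterError(
                "repurposed_visits_per_patient cannot exceed "
                "routine_visits_per_year")

    @property
    def annual_session_capacity(self) -> float:
        """Education sessions one FTE can deliver per year."""
        return annual_session_capacity(self.sessions_per_day,
                                       self.days_per_week,
                                       self.weeks_per_year)

    @property
    def contacts_per_session(self) -> int:
        """Telemedicine contacts fitting in one routine session (floored)."""
        return int(self.routine_minutes // self.tele_minutes)

    def replace(self, **changes) -> "ClinicParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class BaseCaseResult:
    """Status-quo clinic economics.

    ``fte_needed`` and ``labor_cost`` are unrounded; the ``*_display``
    companions round half-up to two decimals and to the dollar, the
    precision the figures are published at. The displayed labor cost is
    derived from the unrounded FTE (rounding the FTE first would
    overstate labor by ~$200 at the defaults).
    """

    marginal_revenue: float
    appointments_needed: float
    annual_session_capacity: float
    fte_needed: float
    labor_cost: float

    @property
    def fte_display(self) -> float:
        return round_half_up(self.fte_needed, 2)

    @property
    def labor_cost_display(self) -> float:
        return round_half_up(self.labor_cost, 0)


def annual_session_capacity(sessions_per_day: float, days_per_week: float,
                            weeks_per_year: float) -> float:
    """Annual education-session capacity of one FTE (product of factors)."""
    if min(sessions_per_day, days_per_week, weeks_per_year) < 0:
        raise InvalidParameterError("capacity factors must be >= 0")
    return sessions_per_day * days_per_week * weeks_per_year


def education_revenue(n_patients: float, visits_per_year: float,
                      rate: float) -> float:
    """Annual marginal reimbursement revenue from education visits."""
    return n_patients * visits_per_year * rate


def fte_required(appointments_needed: float, annual_capacity: float) -> float:
    """Unrounded FTE needed to deliver ``appointments_needed`` sessions."""
    if annual_capacity <= 0:
        raise InvalidParameterError("annual capacity must be > 0")
    return appointments_needed / annual_capacity


def labor_cost(fte_unrounded: float, salary: float) -> float:
    """Annual marginal labor cost; uses the unrounded FTE."""
    return fte_unrounded * salary


def build_base_case(params: ClinicParameters) -> BaseCaseResult:
    """Assemble the status-quo base case from clinic parameters."""
    capacity = params.annual_session_capacity
    appointments = params.n_patients * params.routine_visits_per_year
    fte = fte_required(appointments, capacity)
    return BaseCaseResult(
        marginal_revenue=education_revenue(params.n_patients,
                                           params.routine_visits_per_year,
                                           params.routine_rate),
        appointments_needed=appointments,
        annual_session_capacity=capacity,
        fte_needed=fte,
        labor_cost=labor_cost(fte, params.cdces_salary),
    )
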