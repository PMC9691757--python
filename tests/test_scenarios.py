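"""Adoption scenarios, break-even rates, and their closed-form identities."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpmecon import (ClinicParameters, InvalidParameterError, NoContactsError,
                     apply_outcome_offset, break_even_rate,
                     break_even_rate_brute_force, compare_scenarios,
                     contacts_needed, education_revenue,
                     freed_contacts, revenue_gap, run_augmented_capacity,
                     run_capacity_neutral, telemedicine_capacity)
from rpmecon._rounding import round_half_up
from rpmecon.scenarios import BreakEvenNotFoundError


@st.composite
def clinic_params(draw, with_offset=False):
    """Random valid parameter sets in clinically plausible ranges."""
    visits = draw(st.integers(min_value=2, max_value=8))
    routine_min = draw(st.integers(min_value=10, max_value=60))
    gap_cap = 0.0
    if with_offset:
        gap_cap = draw(st.floats(min_value=0, max_value=30))
    return ClinicParameters(
        n_patients=draw(st.integers(min_value=10, max_value=400)),
        routine_visits_per_year=visits,
        routine_rate=draw(st.integers(min_value=20, max_value=200)),
        cdces_salary=draw(st.integers(min_value=30_000, max_value=150_000)),
        sessions_per_day=draw(st.integers(min_value=3, max_value=8)),
        days_per_week=draw(st.integers(min_value=3, max_value=6)),
        weeks_per_year=draw(st.integers(min_value=40, max_value=52)),
        routine_minutes=routine_min,
        tele_minutes=draw(st.integers(min_value=1, max_value=routine_min)),
        rpm_rate=draw(st.integers(min_value=0, max_value=100)),
        repurposed_visits_per_patient=draw(
            st.integers(min_value=1, max_value=visits - 1)),
        coverage_by_year=tuple(draw(st.lists(
            st.floats(min_value=0.05, max_value=1.0),
            min_size=1, max_size=3))),
        hba1c_value_per_patient=gap_cap,
    )


# --- elementary operations -------------------------------------------------

@pytest.mark.parametrize("args, expected", [
    ((100, 30, 5), 600),    # six 5-min contacts per repurposed session
    ((100, 30, 30), 100),   # one-for-one swap
    ((100, 30, 7), 400),
])
def test_freed_contacts(args, expected):
    assert freed_contacts(*args) == expected


def test_freed_contacts_matches_slot_enumeration():
    """Whole contacts per session = count of k with k*tele <= routine."""
    for routine in range(5, 61, 5):
        for tele in range(1, routine + 1):
            slots = sum(1 for k in range(1, routine + 1)
                        if k * tele <= routine)
            assert freed_contacts(1, routine, tele) == slots


def test_freed_contacts_zero_tele_minutes():
    with pytest.raises(InvalidParameterError):
        freed_contacts(100, 30, 0)


@pytest.mark.parametrize("args, expected", [
    ((100, 56), 5600),
    ((0, 56), 0),
    ((150, 84), 12600),
])
def test_revenue_gap(args, expected):
    assert revenue_gap(*args) == expected


def test_revenue_gap_equals_lost_education_revenue():
    assert revenue_gap(150, 84) == education_revenue(150, 1, 84)


@pytest.mark.parametrize("args, expected", [
    ((5600, 0, 100), 5600),
    ((5600, 56, 100), 0),     # offset cancels the gap exactly
    ((5600, 28, 100), 2800),
])
def test_apply_outcome_offset(args, expected):
    assert apply_outcome_offset(*args) == expected


def test_outcome_offset_halves_break_even(defaults):
    """A $28/patient HbA1c value halves the capacity-neutral rate."""
    half = run_capacity_neutral(
        defaults.replace(hba1c_value_per_patient=28.0))
    assert half.break_even_rate == pytest.approx(9.33 / 2, abs=0.01)
    scanned = break_even_rate_brute_force(
        lambda rate: rate * 600 - 2800, upper_bound=56.0)
    assert scanned == half.break_even_rate


@pytest.mark.parametrize("args, expected", [
    ((5600, 600), 9.33),
    ((0, 600), 0.00),
    ((9807.69, 900), 10.90),
])
def test_break_even_rate(args, expected):
    assert break_even_rate(*args) == expected


def test_break_even_rate_no_contacts():
    with pytest.raises(NoContactsError):
        break_even_rate(5600, 0)


# --- brute-force oracle ----------------------------------------------------

def test_brute_force_capacity_neutral(defaults):
    result = run_capacity_neutral(defaults)
    scanned = break_even_rate_brute_force(
        lambda rate: rate * result.freed_contacts - result.revenue_gap,
        upper_bound=56.0)
    assert scanned == 9.33


def test_brute_force_augmented_year1(defaults):
    year1 = run_augmented_capacity(defaults)[0]
    scanned = break_even_rate_brute_force(
        lambda rate: rate * year1.contacts_needed
        - year1.additional_labor_display, upper_bound=56.0)
    assert scanned == 10.90


def test_brute_force_zero_gap():
    assert break_even_rate_brute_force(lambda rate: rate * 600) == 0.0


def test_brute_force_no_solution():
    with pytest.raises(BreakEvenNotFoundError):
        break_even_rate_brute_force(lambda rate: -1.0, upper_bound=1.0)


@given(clinic_params())
@settings(max_examples=25, deadline=None)
def test_brute_force_agrees_with_closed_form(params):
    neutral = run_capacity_neutral(params)
    scanned = break_even_rate_brute_force(
        lambda rate: rate * neutral.freed_contacts - neutral.revenue_gap,
        upper_bound=params.routine_rate + 1)
    assert abs(scanned - neutral.break_even_rate) <= 0.01

    year1 = run_augmented_capacity(params)[0]
    scanned = break_even_rate_brute_force(
        lambda rate: rate * year1.contacts_needed
        - year1.additional_labor_display,
        upper_bound=params.cdces_salary / params.annual_session_capacity + 1)
    assert abs(scanned - year1.break_even_rate) <= 0.01


# --- capacity-neutral scenario --------------------------------------------

def test_capacity_neutral_reference_values(defaults):
    r = run_capacity_neutral(defaults)
    assert (r.remaining_visits_per_patient, r.remaining_revenue,
            r.revenue_gap, r.repurposed_appointments, r.freed_contacts,
            r.break_even_rate, r.rpm_revenue, r.margin) == \
        (3, 16800, 5600, 100, 600, 9.33, 21000, 15400)


def test_capacity_neutral_nothing_repurposed(defaults):
    r = run_capacity_neutral(
        defaults.replace(repurposed_visits_per_patient=0))
    assert r.revenue_gap == 0
    assert r.margin == 0
    assert r.break_even_rate is None


def test_capacity_neutral_one_for_one_swap(defaults):
    """A 30-min contact frees one slot per visit: break-even = routine rate."""
    r = run_capacity_neutral(defaults.replace(tele_minutes=30.0))
    assert r.freed_contacts == 100
    assert r.break_even_rate == 56.00
    scanned = break_even_rate_brute_force(
        lambda rate: rate * 100 - 5600, upper_bound=100.0)
    assert scanned == 56.00


# --- augmented-capacity scenario ------------------------------------------

@pytest.mark.parametrize("args, expected", [
    ((100, 0.75, 12), 900),
    ((100, 0.50, 12), 600),
    ((100, 0, 12), 0),
])
def test_contacts_needed(args, expected):
    assert contacts_needed(*args) == expected


@pytest.mark.parametrize("args, expected", [
    ((1300, 30, 5), 7800),
    ((1300, 30, 30), 1300),
    ((1950, 30, 5), 11700),
])
def test_telemedicine_capacity(args, expected):
    assert telemedicine_capacity(*args) == expected


def test_augmented_reference_values(defaults):
    year1, year2 = run_augmented_capacity(defaults)
    assert (year1.coverage, year1.contacts_needed,
            year1.telemedicine_capacity, year1.additional_fte_display,
            year1.additional_labor_display, year1.break_even_rate,
            year1.rpm_revenue, year1.margin) == \
        (0.75, 900, 7800, 0.12, 9808, 10.90, 31500, 21692)
    assert (year2.coverage, year2.contacts_needed,
            year2.additional_fte_display, year2.additional_labor_display,
            year2.break_even_rate, year2.margin) == \
        (0.50, 600, 0.08, 6538, 10.90, 14462)


def test_augmented_full_coverage(defaults):
    (year,) = run_augmented_capacity(
        defaults.replace(coverage_by_year=(1.0,)))
    assert year.contacts_needed == 1200
    assert year.additional_fte == pytest.approx(1200 / 7800)
    assert year.additional_labor_cost == pytest.approx(
        1200 / 7800 * defaults.cdces_salary)


def test_augmented_zero_coverage_year(defaults):
    (year,) = run_augmented_capacity(defaults.replace(
        coverage_by_year=(0.0,)))
    assert year.contacts_needed == 0
    assert year.break_even_rate is None


def test_augmented_empty_coverage_list(defaults):
    with pytest.raises(InvalidParameterError):
        run_augmented_capacity(defaults.replace(coverage_by_year=()))


# --- comparison ------------------------------------------------------------

def test_compare_scenarios_reference(defaults):
    rows = compare_scenarios(defaults).rows
    assert rows["Minimum reimbursement rate per telemedicine appointment"] \
        == ("N/A", 9.33, 10.90)
    assert rows["Routine appointments repurposed for telehealth"] \
        == ("N/A", 100, 0)
    assert rows["Additional marginal CDCES labor costs"] == ("N/A", 0, 9808)
    assert rows["Routine visits per patient per year"] == (4, 3, 4)


def test_compare_scenarios_zero_clinic(defaults):
    rows = compare_scenarios(defaults.replace(n_patients=0)).rows
    for label, cells in rows.items():
        for cell in cells:
            assert cell == "N/A" or float(cell) >= 0


# --- invariants ------------------------------------------------------------

@given(clinic_params())
@settings(max_examples=40, deadline=None)
def test_capacity_neutral_closed_form_identity(params):
    """Break-even = routine_rate / floor(d_r/d_t); independent of N,
    salary, capacity, and repurposed count."""
    ratio = int(params.routine_minutes // params.tele_minutes)
    expected = round_half_up(params.routine_rate / ratio, 2)
    assert run_capacity_neutral(params).break_even_rate == expected


@given(clinic_params())
@settings(max_examples=40, deadline=None)
def test_augmented_closed_form_identity(params):
    """Break-even ~ salary / telemedicine capacity (dollar rounding of the
    labor cost moves it by less than a cent), equal across years."""
    capacity = telemedicine_capacity(params.annual_session_capacity,
                                     params.routine_minutes,
                                     params.tele_minutes)
    expected = params.cdces_salary / capacity
    years = run_augmented_capacity(params)
    # dollar rounding of the labor cost moves the rate by <= $0.5/contacts
    tols = [0.5 / y.contacts_needed + 0.0051 for y in years]
    for year, tol in zip(years, tols):
        assert year.break_even_rate == pytest.approx(expected, abs=tol)
    rates = [y.break_even_rate for y in years]
    assert max(rates) - min(rates) <= 2 * max(tols)


@given(clinic_params(with_offset=True))
@settings(max_examples=40, deadline=None)
def test_revenue_neutrality_at_break_even(params):
    """Billing at the break-even rate restores the base-case margin up to
    cent rounding of the rate."""
    neutral = run_capacity_neutral(params)
    change = neutral.break_even_rate * neutral.freed_contacts \
        - neutral.revenue_gap
    assert abs(change) <= neutral.freed_contacts * 0.005 + 1e-9

    for year in run_augmented_capacity(params):
        if year.break_even_rate is None:
            continue
        net = apply_outcome_offset(year.additional_labor_display,
                                   params.hba1c_value_per_patient,
                                   params.n_patients)
        change = year.break_even_rate * year.contacts_needed - net
        assert abs(change) <= year.contacts_needed * 0.005 + 1e-9


@given(clinic_params(), st.integers(min_value=1, max_value=10))
@settings(max_examples=40, deadline=None)
def test_break_even_monotone_in_duration_ratio(params, shorter):
    """Shorter telemedicine contacts never raise the break-even rate."""
    tele = min(params.tele_minutes, shorter)
    faster = run_capacity_neutral(params.replace(tele_minutes=tele))
    assert faster.break_even_rate \
        <= run_capacity_neutral(params).break_even_rate


@given(clinic_params(), st.floats(min_value=0, max_value=100))
@settings(max_examples=40, deadline=None)
def test_break_even_monotone_in_outcome_value(params, value):
    with_value = run_capacity_neutral(
        params.replace(hba1c_value_per_patient=value))
    assert with_value.break_even_rate \
        <= run_capacity_neutral(params).break_even_rate


@given(clinic_params(), st.floats(min_value=1, max_value=3))
@settings(max_examples=40, deadline=None)
def test_augmented_break_even_linear_in_salary(params, factor):
    base = run_augmented_capacity(params)[0]
    scaled = run_augmented_capacity(
        params.replace(cdces_salary=params.cdces_salary * factor))[0]
    tol = (0.5 / base.contacts_needed + 0.0051) * (1 + factor)
    assert scaled.break_even_rate == pytest.approx(
        factor * base.break_even_rate, abs=tol)


@given(clinic_params(with_offset=True))
@settings(max_examples=40, deadline=None)
def test_margin_gap_conservation(params):
    """Margin plus gap (or dollar-rounded labor) re-assembles RPM revenue."""
    neutral = run_capacity_neutral(params)
    assert neutral.margin + neutral.revenue_gap == neutral.rpm_revenue
    for year in run_augmented_capacity(params):
        assert year.margin + year.additional_labor_display \
            == year.rpm_revenue
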