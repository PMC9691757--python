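# Methods

## Model structure and assumptions

`rpmecon` is a deterministic, desk-scale decision model of the yearly
*marginal* costs and revenues of CDCES-delivered diabetes education in a
pediatric type 1 diabetes clinic, and of two pathways for adding
algorithm-enabled telemedicine on top of it. Everything is annual, in
plain USD, with no discounting across the two-year augmented-capacity
horizon. Out of scope by construction:

* one-time fixed costs (software, hardware, EMR integration, training);
* revenue from non-CDCES staff (endocrinologists, dieticians), which is
  unchanged across scenarios;
* billing-code mechanics beyond a single average rate per encounter type
  (e.g. per-month frequency limits on CGM-interpretation codes);
* estimation of clinical effect — the HbA1c improvement is a user-supplied
  dollar value, not a modelled outcome;
* per-patient scheduling: flexible contacts are allocated in aggregate,
  so some patients may receive many and others none.

FTE is continuous (no integer head-count constraint), matching how the
reference figures are printed (0.31, 0.12 FTE).

## Parameters

All fields of `ClinicParameters` are modifiable; defaults are the
reference clinic.

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `n_patients` | 100 | patients | cohort size |
| `routine_visits_per_year` | 4 | visits/patient/yr | quarterly education |
| `routine_rate` | 56 | USD/visit | 2022 Medicare average, 30-min self-management training |
| `cdces_salary` | 85,000 | USD/yr | national average, full-time |
| `sessions_per_day` × `days_per_week` × `weeks_per_year` | 5 × 5 × 52 | sessions/yr | 1,300-session annual capacity per FTE |
| `routine_minutes` / `tele_minutes` | 30 / 5 | min | floored ratio = contacts per repurposed session |
| `rpm_rate` | 35 | USD/contact | 2022 Medicare average, CGM analysis & interpretation |
| `repurposed_visits_per_patient` | 1 | visits/patient/yr | capacity-neutral scenario |
| `coverage_by_year` | (0.75, 0.50) | fraction/period | augmented scenario, years 1–2 |
| `periods_per_year` | 12 | periods | monthly billing cadence |
| `hba1c_value_per_patient` | 0 | USD/patient/yr | value of a 0.5% HbA1c improvement |

Review periods are monthly in the financial model even though the
clinical triage runs weekly; the contact arithmetic (50 or 75 per month)
is defined at the monthly cadence, and which cadence governs billing
eligibility is left to the user.

The HbA1c offset multiplies the per-patient value by the *full*
population, not only contacted patients, since the value is defined "on
average per patient"; a clinic that prefers the narrower base can fold
the ratio into the value itself.

## Numerical conventions

* **Rounding.** All arithmetic is unrounded; display values round
  *half-up* at the published precision — annual dollar totals to the
  dollar, per-contact rates to the cent, FTE to two decimals. This is the
  only policy that reproduces every reference figure (e.g. labor
  $26,153.85 → $26,154; 10.8977 → $10.90). Labor cost is always derived
  from the *unrounded* FTE; rounding the FTE first would give $26,350.
* **Augmented margins and break-evens** use the *dollar-rounded* labor
  cost ($31,500 − $9,808 = $21,692), again matching the published
  convention. Consequently the augmented break-even can differ from the
  exact closed form $s/(Ck)$ by up to $0.5/\text{contacts}$.
* **Duration perturbations** change only the session→contact conversion
  ratio $k$, never the annual session capacity: a 45-minute visit still
  consumes one of 1,300 sessions but frees 9 contacts.
* **Per-period coverage demand** rounds to the nearest whole patient
  before annualizing.
* **Degenerate inputs.** A break-even rate with zero contacts is an
  error (`NoContactsError`), not zero — a per-contact rate is undefined
  without contacts; scenario runners return `None` ("N/A") instead of
  raising when the degenerate case arises naturally (nothing repurposed,
  zero coverage). Zero `tele_minutes` and negative quantities are
  rejected at construction.
* **Break-even grid scan.** `break_even_rate_brute_force` is an
  independent check on the closed forms: it walks the cent grid until the
  margin change versus the base case turns non-negative and returns the
  grid point nearer the zero crossing (ties upward, with a small
  float-tolerant band so exact half-cent ties resolve like half-up
  rounding). Returning the *first* non-negative grid point instead would
  bias the result up by one cent whenever the exact break-even rounds
  down (9.33̅ → $9.34 rather than the published $9.33). Currency is kept
  in floats; the scan's grid is indexed by integer cents, so no float
  drift accumulates along it.
* **Revenue-neutrality** at the cent-rounded break-even rate holds up to
  the rounding itself: the margin change versus the base case is within
  ± contacts × $0.005.

## Sensitivity analysis

One parameter at a time, default multipliers {1.5, 0.5}; no tornado
ordering, two-way grids, or probabilistic analysis. "CDCES capacity" is a
single virtual knob scaling the annual session capacity (implemented via
the weeks-per-year factor); "coverage" scales all per-year fractions,
clamped at 1 to respect the [0, 1] invariant (the augmented break-even is
independent of coverage, so the clamp never distorts a result). Two exact
identities make the reported insensitivities testable rather than
approximate: the capacity-neutral break-even equals $r/k$ (independent of
$N$, salary, capacity, repurposed count) and the augmented break-even
equals $s/(Ck)$ up to labor rounding (independent of $N$, coverage, the
routine rate).

## Synthetic demand generator

The generator asks whether the deterministic model's *full-booking*
assumption survives stochastic patient flagging.

* **Bernoulli model**: each patient-period is flagged independently with
  probability $p$ (default scenarios: 0.5 and 0.75, the coverage
  fractions the financial model assumes).
* **CGM-metric model**: per patient-period, a time-in-range fraction and
  a sensor-wear fraction are drawn from Beta distributions and the triage
  rule (TIR < 0.65 **or** wear < 0.50) is applied. Defaults
  TIR ~ Beta(3.2, 1.8), wear ~ Beta(6, 1.5) give a marginal flag
  probability of 0.500, i.e. the steady-state coverage assumption. Point
  masses (`(None, value)`) support deterministic checks.

Demand is served greedily up to a fixed per-period capacity. With 100
patients, Bernoulli(0.5) flags and the capacity-neutral 50 contacts/month,
expected utilization is $E[\min(X, 50)]/50 \approx 0.968$ for
$X \sim \mathrm{Bin}(100, 0.5)$ — high, but not the 100% the deterministic
model books, and the shortfall is what `utilization_summary` quantifies.
The tests verify the Monte-Carlo mean against this exact binomial
expectation (10,000 replicates, 99% bounds) and that degenerate draws
reproduce the deterministic RPM revenue exactly.

What the generator does **not** emulate: within-patient persistence of
poor control (flags are independent across periods, so real demand is
likely more correlated and lumpier than simulated demand), hypoglycemia
flags as a separate stream, seasonal or new-onset effects, and
glucose-trace-level CGM data. Passing tests therefore show internal
consistency of the capacity arithmetic under independent flagging, not
that a real clinic's demand would behave this way.

## Problem sizes

Everything is desk-scale: scenario evaluations are closed-form arithmetic
(< 1 ms), the randomized oracle-equivalence check uses 1,000 parameter
sets, and the utilization calibration uses 10,000 replicates of a
100-patient year — the full suite runs in seconds.

## Limitations

Beyond the scope exclusions above: a single average reimbursement rate
stands in for payer mix; year-2 capacity reduction is assumed frictionless
(no severance or retraining cost); and the model treats demand and
capacity as exactly divisible, so very small clinics (a handful of
contacts per period) will see rounding dominate the break-even rate.
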