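# rpmecon

Financial planning for **algorithm-enabled remote patient monitoring (RPM)**
in pediatric type 1 diabetes clinics.

Clinics that review continuous glucose monitor (CGM) data for their whole
population — flagging patients whose time-in-range falls below 65% or whose
sensor wear drops below 50% and sending them brief message-based
interventions — can reach far more patients per staff-hour than quarterly
education visits allow. But fee-for-service reimbursement is built around
those visits, so the question a clinic manager actually faces is: *what is
the minimum per-contact telemedicine reimbursement at which switching does
not hurt the bottom line?* `rpmecon` answers that question for two adoption
pathways, with every parameter modifiable.

## The model

A clinic serves $N$ patients with $v$ routine diabetes-education visits per
patient-year, each reimbursed at rate $r$ and delivered by Certified
Diabetes Care and Education Specialists (CDCES) earning salary $s$, with an
annual capacity of $C$ sessions per full-time equivalent (FTE). A routine
visit lasts $d_r$ minutes; a message-based telemedicine contact $d_t$, so
one repurposed session accommodates $k = \lfloor d_r / d_t \rfloor$
contacts.

* **Base case** — marginal revenue $Nvr$; labor cost $\frac{Nv}{C}\,s$.
* **Capacity-neutral** — repurpose $\rho$ visits per patient as flexible
  contacts: revenue gap $G = N\rho r$, freed contacts $T = N\rho k$,
  break-even rate $b = G / T = r / k$.
* **Augmented-capacity** — keep all visits, add capacity to contact a
  fraction $f_y$ of patients in each of 12 monthly review periods:
  $Q_y = \mathrm{round}(N f_y)\cdot 12$ contacts need $Q_y / (Ck)$ extra
  FTE, costing $\Delta L_y$; break-even $b = \Delta L_y / Q_y = s/(Ck)$.
* A clinic may credit a per-patient dollar value $H$ for the 0.5% HbA1c
  improvement associated with the program; $NH$ is subtracted from the gap
  before solving (floored at zero).

A one-way sensitivity module perturbs any single parameter, and a
synthetic-demand simulator (independent Bernoulli flags, or Beta-distributed
TIR/wear metrics pushed through the triage rule) stress-tests the model's
assumption that flexible capacity is fully booked every period.

## Worked example

At the default parameters (100 patients, 4 × $56 visits/year, $85,000
salary, 1,300-session capacity, 30- vs 5-minute durations):

```sh
$ rpmecon base-case
| Base case | Value |
|---|---|
| Number of patients in practice | 100 |
| Routine visits per patient per year | 4 |
| Reimbursement rate per routine visit | $56.00 |
| Marginal Reimbursement Revenue | $22,400 |
| Annual CDCES salary | $85,000 |
| CDCES capacity (appointments per year) | 1,300 |
| Total appointments needed (per year) | 400 |
| FTE needed | 0.31 |
| Total CDCES labor costs | $26,154 |
```

Education brings in $22,400/year and consumes 0.31 FTE ($26,154 of labor).
Repurposing one visit per patient (capacity-neutral) forfeits $5,600 of
revenue but frees 600 five-minute contacts, so each contact need only earn
**$9.33** to break even — and at the current $35 RPM rate (CGM analysis and
interpretation) would instead add a $15,400 margin:

```sh
$ rpmecon capacity-neutral   # Revenue Gap $5,600; 600 contacts;
                             # break-even $9.33; margin $15,400
$ rpmecon augmented          # Year 1: 900 contacts, +0.12 FTE, +$9,808
                             # labor, break-even $10.90, margin $21,692
$ rpmecon sensitivity --scenario capacity-neutral
| Baseline                       | 1.00 | $9.33  | no  |
| 50% increase in routine_rate   | 1.50 | $14.00 | yes |
| 50% decrease in routine_rate   | 0.50 | $4.67  | yes |
| 50% increase in routine_minutes| 1.50 | $6.22  | yes |
| 50% decrease in routine_minutes| 0.50 | $18.67 | yes |
...
```

The break-even rate is insensitive to population size, salary and capacity
in the capacity-neutral pathway (it is exactly $r/k$), and insensitive to
coverage and the routine rate in the augmented pathway (it is $s/(Ck)$).
Both sit comfortably below the ~$10–11 level, which is itself well under
current RPM reimbursement.

Every parameter can be overridden in a flat YAML config
(`rpmecon base-case --config myclinic.yaml`); see
`src/rpmecon/data/defaults.yaml` for the keys. `rpmecon simulate-demand`
runs the stochastic flagging simulator and reports capacity utilization.

## Layout

| Module | Contents |
|---|---|
| `rpmecon.clinic_model` | `ClinicParameters`, base-case economics |
| `rpmecon.scenarios` | both adoption scenarios, break-even solving, scenario comparison |
| `rpmecon.sensitivity` | one-way perturbations of any parameter |
| `rpmecon.synthetic_demand` | stochastic flag simulation, utilization statistics |
| `rpmecon.config` / `rpmecon.reporting` / `rpmecon.cli` | YAML config, CSV/Markdown tables, command line |

See `docs/methods.md` for modelling assumptions, rounding conventions and
limitations.
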