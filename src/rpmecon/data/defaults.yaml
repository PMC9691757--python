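# Reference parameter set: a 100-patient pediatric T1D clinic with
# quarterly CDCES education visits. Any key may be overridden in a user
# config; see rpmecon.config.RunConfig for the non-clinic keys.
n_patients: 100
routine_visits_per_year: 4
routine_rate: 56.0
cdces_salary: 85000.0
sessions_per_day: 5
days_per_week: 5
weeks_per_year: 52
routine_minutes: 30.0
tele_minutes: 5.0
rpm_rate: 35.0
repurposed_visits_per_patient: 1
coverage_by_year: [0.75, 0.50]
periods_per_year: 12
hba1c_value_per_patient: 0.0
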