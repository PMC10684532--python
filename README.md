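# screenopt

Optimization of risk-stratified cancer screening intervals under a resource
constraint. Given a population distribution of short-term invasive-cancer risk
(summarised as K equal-count quantiles of a risk-score distribution), a set of
candidate screening intervals, and a deterministic natural-history model for
the chance a cancer is screen-detected versus diagnosed in the interval
between screens, `screenopt`:

- computes per-quantile, per-regimen advanced-cancer (node-positive) risk
  `p = r * (a*s + b*(1-s))`, where `s` is the closed-form screen-detected
  fraction for an exponential sojourn model;
- solves the budget-constrained assignment of regimens to quantiles as a
  linear programme (fractional shares; an exact integer programme is also
  available for cohort-level use), minimizing expected advanced-cancer
  incidence subject to one regimen per quantile and a cap on total screens;
- maps optimal assignments back to risk-score thresholds, sweeps the budget to
  trace benefit-versus-resource curves, and runs sensitivity scenarios on the
  stage-mix and detection parameters;
- generates synthetic case-control risk-score samples (cases enriched at high
  risk) for testing and demonstration.

## Command line

```sh
# detection-mode / node-positive table per screening interval
screenopt table1 --out table1.csv

# synthetic case-control sample, then optimize at the triennial-for-all budget
screenopt synth --out sample.csv --seed 3 --n-cases 2044 --n-controls 2044
screenopt optimize --config config.yaml --out run/
screenopt sweep --config config.yaml --out sweep.csv --grid 0.6:1.6:0.05
screenopt sensitivity --config config.yaml --out sensitivity.csv
```

A config file (YAML or JSON) names the model parameters, regimens and exactly
one risk-input source:

```yaml
lambda_rate: 0.25        # asymptomatic -> symptomatic transitions / year
sensitivity: 0.92        # per-screen detection probability
adv_frac_screen: 0.22    # P(advanced | screen-detected)
adv_frac_interval: 0.53  # P(advanced | interval cancer)
horizon_years: 6
K: 100
baseline_label: 3y
scores_csv: sample.csv   # or quantiles_csv: centiles.csv
regimens:
  - {interval_years: 1}  # cost defaults to horizon / interval
  - {interval_years: 3}
  - {interval_years: 4}
```

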