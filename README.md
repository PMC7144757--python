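# ruletrial

Optimize a prediction-based treatment decision rule and evaluate its
**clinical utility** — the improvement in patient outcomes it causes, not
just its predictive accuracy — by emulating the randomized target trial in
observational cohort data.

The motivating setting is a disease register of newly diagnosed Crohn's
disease patients: a prognostic model predicts each patient's risk of major
abdominal surgery within 5 years, and a decision rule maps that risk to a
treatment in the action space {A = thiopurine monotherapy, B = thiopurine +
biologic combination therapy}, e.g. "escalate to combination therapy when
risk ≥ 0.3". Before such a rule is used (or a confirmatory trial is
funded), one wants evidence that using it would beat the standard of care.
The package is for biostatisticians and epidemiologists who have a
subject-level observational cohort and want that evidence, with honest
uncertainty, from a pre-specified emulated trial.

## The estimand and the estimator

The target trial randomizes eligible subjects at time zero (diagnosis)
between rule-based care and standard of care. Its intention-to-treat
estimand is

```
Δ = E[Y^pred] − E[Y^soc]
```

with Y the binary event indicator within the horizon. In observational data:

* `E[Y^soc]` is the event proportion of the whole eligible population
  (they factually received standard care) — no modelling;
* `E[Y^pred]` decomposes over the rule's risk strata,
  `P(low)·E[Y^a_low | low] + P(high)·E[Y^a_high | high]`, each stratum mean
  estimated by **g-computation**: fit the Q model (logistic outcome
  regression on treatment + confounders) within the stratum, predict every
  subject with treatment set to the rule's assignment, and average.

Subjects whose event occurs within the grace period (the allowed window
from time zero to treatment start, default 14 days) are counted in **both
arms** with their factual outcome, avoiding survivor bias. Confidence
intervals come from a nonparametric bootstrap that resamples whole
subjects — both arms share subjects, and the resampling unit preserves that
dependence. Because cutoff selection and rule optimization are data driven,
the pipeline splits the cohort into train / optimize / validate partitions
and the emulated trial only ever sees the validation split.

A synthetic-cohort simulator with known potential outcomes (shared-uniform
draws, so each subject's two potential outcomes are jointly defined)
provides exact ground truth for every estimator in the package; all
statistical guarantees in the test suite are checked against it.

See `docs/methods.md` for the model, assumptions, conventions, and
limitations.

## Worked example

Simulate a confounded register-like cohort (sicker patients receive
combination therapy more often, combination therapy lowers the event odds),
then run the full three-way split pipeline:

```python
import ruletrial as rt

config = {
    "seed": 7,
    "data": {"simulate": {
        "n_subjects": 10_000,
        "covariates": [{"name": "x", "family": "bernoulli", "params": [0.5]}],
        "risk_coefficients": [-1.2, 1.2],        # log-odds of surgery under A
        "treatment_effect_B_vs_A": -0.8,         # B lowers the log-odds
        "confounding_coefficients": [-1.0, 2.0], # P(B|x): confounding by indication
        "grace_period_days": 14,
        "horizon_days": 1826,
        "seed": 11,
    }},
    "action_space": ["A", "B"],
    "eligibility": {"grace_period_days": 14, "horizon_days": 1826},
    "risk_model": {"covariates": ["x"]},
    "rule": {"cutoff_grid": [0.3, 0.35, 0.4],
             "constraints": [["low", "B"]]},     # expert opinion: no escalation for low risk
    "q_model": {"covariates": ["x"]},
    "split": {"mode": "three-way", "fractions": [1/3, 1/3, 1/3]},
    "bootstrap": {"n_boot": 500, "level": 0.95},
}
pipe = rt.run_pipeline(config)
print(pipe.report)
```

which prints:

```
Emulated target trial: prediction-based decision rule vs standard of care
==========================================================================
run seed: 7
split mode: three-way; fractions: (0.3333333333333333, 0.3333333333333333, 0.3333333333333333)
eligible subjects: 10000
eligibility exclusions: {}

prognostic model (fitted-internally):
  (intercept): -1.2965
  x: +0.6326

decision rule: risk < 0.3 -> A; risk >= 0.3 -> B

emulated trial estimates:
  n eligible (validation): 3334  [low: 1691, high: 1643, early events: 1]
  stratum weights: low 0.507, high 0.493
  rule-arm mean     E[Y^pred] = 0.2870
  standard-of-care  E[Y^soc]  = 0.2915
  delta (ITT contrast)        = -0.0045
  95% percentile CI: [-0.0145, +0.0047] (500 replicates, 0 failed)

positivity: 0 hard flag(s), 0 sparse cell(s)
```

Reading it: the prognostic model was fitted on the training third (its
slope is attenuated relative to the generating value because treatment
partially offsets the risk x confers — that is what a prognostic model
fitted on treated patients looks like); the optimizer, constrained to
never give combination therapy to low-risk patients, chose the cutoff 0.3
rule; on the untouched validation third the rule's estimated event
proportion is 0.287 versus 0.292 under standard of care, an estimated
absolute reduction of 0.45 percentage points whose 95% interval includes
zero — in this run the data do not establish superior clinical utility,
which is exactly the kind of verdict the emulation is for. Since standard
of care in this simulated register already escalates most high-risk
patients, a small Δ is the true state of affairs here.

The same stages are available as a CLI (`ruletrial simulate / fit-risk /
optimize-rule / emulate / run`, each with `--config/--seed/--out`) and as
library functions (`simulate_cohort`, `fit_risk_model`,
`predictiveness_curve`, `select_cutoff`, `enumerate_rules`,
`optimize_rule`, `estimate_delta`, `bootstrap_delta`, `split_sample`).

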