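# Methods

`ruletrial` evaluates the *clinical utility* of a prediction-based
treatment decision rule — does treating according to a prognostic risk
score improve patient outcomes relative to the standard of care? — by
emulating the randomized target trial that would answer the question
directly, using observational cohort data. The running design emulates a
disease register of newly diagnosed patients (the motivating setting is
Crohn's disease, where the adverse outcome is major abdominal surgery
within 5 years and the actions are thiopurine monotherapy `A` versus
thiopurine + biologic combination therapy `B`), but every component is
generic over covariates, action labels, horizon, and utility.

## The estimand and its decomposition

In the target trial, eligible subjects would be randomized at time zero
(diagnosis) to either "treat according to the rule" or "usual care". The
intention-to-treat estimand is

    delta = E[Y^pred] − E[Y^soc],

where `Y^pred` and `Y^soc` are potential binary outcomes (event within the
horizon) under rule-based and usual care. In observational data nobody was
randomized, so the two arms are reconstructed differently:

* **Standard of care.** The observed eligible population *received*
  standard care, so `E[Y^soc]` is estimated by the plain event proportion
  over all eligible subjects — no model, no extra assumptions.
* **Rule arm.** A deterministic rule `risk >= c ⇒ treatment a_high`,
  `risk < c ⇒ a_low` induces two strata, and

      E[Y^pred] = P(low) · E[Y^{a_low} | low] + P(high) · E[Y^{a_high} | high].

  The stratum probabilities are empirical frequencies. The conditional
  potential-outcome means are estimated by **g-computation**: within the
  stratum, fit the Q model — a logistic regression of the outcome on the
  received treatment and measured confounders (optionally with
  treatment × covariate interactions) — then predict every subject's
  outcome with treatment *set* to the rule's assignment and average the
  predictions.

Identification requires, within each stratum: positivity of treatment
assignment in every covariate subgroup, no unmeasured confounding, and a
correctly specified Q model. The first is diagnosed by
`emulate.check_positivity` (per-stratum, per-covariate-cell counts of the
assigned treatment; continuous covariates decile-binned; default sparse
floor 5); the other two are untestable in data and are exactly what the
synthetic-cohort validation exercises.

## Time zero and the grace period

All offsets are measured from diagnosis (time zero). Treatment rarely
starts on the day eligibility is met; a **grace period** (default 14 days)
is allowed between time zero and treatment start. Conditioning on
surviving the grace period would bias both arms, so subjects whose event
occurs within the grace window (boundary inclusive, `offset <= grace`)
are counted in **both arms**: they enter the standard-of-care proportion
as ordinary events, and they enter the rule arm with their factual
outcome (Y = 1) at ordinary 1/n weight, bypassing the Q model. They are
excluded from Q-model fitting, since their treatment may be undefined or
irrelevant. Design choice: alternatives (cloning with censoring weights,
down-weighting) exist; the factual-both-arms reading is the simplest one
consistent with counting early events in both arms, and it preserves two
exact invariants that the tests assert — the early/main split partitions
the eligible cohort, and the rule-arm mean equals the weighted sum of its
stratum components to machine precision (strata are defined over *all*
eligible subjects, early events folded into their stratum's mean, so
stratum weights sum to one and `n_low + n_high = n_eligible`).

## The prognostic model and the cutoff

The risk score is a main-effects logistic model of the outcome on baseline
covariates, fitted by maximum likelihood on the training split or supplied
externally (the intended use fixes the prognostic model before the trial
is emulated). Newton fitting is verified to a score norm below 1e-8
per observation; rank-deficient designs and separation raise errors naming
the offending columns rather than returning garbage coefficients.

The low/high cutoff is chosen from the **predictiveness curve**: the
empirical risk quantile function together with the event rate among
subjects above each quantile. Two criteria are offered — target a fraction
of the population to classify as high risk (cutoff = risk quantile at
1 − q), or fix an absolute risk threshold. Both are package choices; no
single "best cutoff" criterion is canonical. Numerical conventions, fixed
package-wide and relied on by the enumerable tests: quantiles interpolate
linearly between order statistics (so the median of 0.1, 0.2, 0.3, 0.4 is
0.25); "high risk" means `risk >= cutoff` (ties go high); the rate above a
threshold uses strictly-greater and reports NaN (not 0) when no subject
lies above.

## Rule optimization

Candidate rules are the Cartesian product of a cutoff grid with the
ordered treatment-pair assignments, minus expert-opinion constraints
(forbidden stratum/treatment pairs, e.g. "no combination therapy for
low-risk patients"), plus the two constant treat-everyone rules kept once
each (at cutoff 1.0) as implicit comparators. Each candidate's event
proportion is estimated with the *same* per-stratum g-computation
estimator used at validation — using a different estimator for
optimization than for validation would optimize the wrong surface. The
utility is a pluggable scalar, minimized; the default is the event
proportion itself, optionally plus per-treatment costs times the fraction
assigned. Ties break toward the larger cutoff (fewer patients escalated —
a least-intervention preference), then lexicographically. Candidates whose
assigned treatment is unobserved in a non-empty stratum are excluded with
a logged warning rather than failing the whole optimization.

## Bootstrap inference

Every eligible subject contributes to the standard-of-care mean and, via
their stratum, to the rule-arm mean, so the two arm estimates are
dependent. The nonparametric bootstrap therefore resamples **subjects**
with replacement from the whole eligible cohort (never per arm) and
re-runs the entire estimation pipeline — the literal same code path as the
point estimate — per replicate. The interval is the percentile interval
(assumption-light and exactly testable in degenerate cases: a constant
outcome yields CI [0, 0]). Replicates that lose within-stratum positivity
or hit separation are dropped and counted rather than retried (retrying
would bias the bootstrap distribution toward positivity-rich resamples);
losing more than 20% of replicates raises an error advising a larger
sample or a coarser Q model.

## Split-sample workflow

Because model fitting and rule optimization are data driven, the emulated
trial must evaluate a *fixed* rule on data those stages never saw. The
orchestration splits the eligible cohort by seeded permutation into
train / optimize / validate fractions (floor-rounded, remainder to
validation, which has the largest evidentiary need). Three modes:
`three-way` (everything internal), `two-way-model-given` (prognostic model
is external information; data split across optimization and validation),
and `validate-only` (the whole rule is external; all data validate it).
The validation partition is passed only to the final stage function, which
tests enforce by tracing which partition each stage receives.

## The synthetic-cohort simulator

The simulator is the package's ground truth. It emulates a register
cohort: baseline covariates (Bernoulli / normal / uniform), logistic
treatment assignment given covariates (non-zero slopes create confounding
by indication), and logistic outcome risk under each treatment, with the
`B` effect optionally interacted with a named covariate to create
qualitative interactions. Both potential outcomes are drawn by comparing a
*single shared uniform draw* per subject against the two risk thresholds,
so individual effects are monotone and the null case gives exactly equal
potential outcomes — which makes the exact value of any rule computable by
`true_rule_value` and keeps it stable as an oracle. Each logical draw
(each covariate, assignment, outcomes, event times, start times) has its
own named substream of the seed, so adding a covariate cannot perturb the
outcome stream.

Defaults encode the register setting: horizon 1826 days (5 years), grace
period 14 days. Event times are uniform on (0, horizon] given an event and
treatment starts uniform on [0, grace] — deliberately simple, since only
the "event within grace" indicator matters downstream; the simulator makes
no claim about real delay laws. Other real-data features it does *not*
emulate: censoring and competing risks, time-varying treatment,
measurement error in covariates, unmeasured confounding (assignment
depends only on covariates the analyst can adjust for), and calendar-time
structure. Passing tests therefore demonstrate the estimators' correctness
*under the identifying assumptions*, not robustness to their violation.

Reference study conditions used throughout the tests and the acceptance
script, both chosen analytically before any estimator ran:

* **Confounded scenario** — severity marker x ~ Bernoulli(0.5); risk under
  A = expit(−1.2 + 1.2 x); B shifts the log-odds by −0.8;
  P(B | x) = expit(−1 + 2x). Closed form: the naive treatment-only
  contrast for the treat-all-B rule is biased by +0.044, while the
  x-adjusted g-computation estimator is consistent.
* **Interaction scenario** — x ~ N(0, 1); risk under
  A = expit(logit(0.3) + x); B shifts the log-odds by −2x, so B helps
  exactly when risk > 0.3 and cutoff 0.3 is the unique optimum among
  {0.2, 0.3, 0.4} (oracle values 0.199 / 0.177 / 0.192 at n = 2·10⁶).

## Numerical and degenerate-input choices

* Logistic fits: `statsmodels` Newton with tight tolerance, then an
  explicit score-norm check; coefficients diverging past 100 (on a
  standardized design) are treated as separation.
* A confounder constant within a fitting stratum is dropped (absorbed by
  the intercept): stratifying on a risk score driven by one covariate
  makes that covariate constant within strata, where it cannot confound.
  Collinearity among *varying* columns still errors.
* A stratum whose fitting subset has a constant outcome short-circuits to
  a constant Q model (the degenerate MLE); a stratum whose only observed
  treatment is exactly the assigned one drops the treatment term
  (outcome-on-covariates) — both are identified cases the strict
  `fit_q_model` contract would reject.
* Empty strata carry weight 0 and a NaN mean; an entirely-early-event
  cohort yields a rule-arm mean of exactly 1.
* Missing covariate values are an error, never imputed.

## Problem sizes

Unit tests run at n ≤ 50 000 single cohorts; the statistical validation
uses 200 replicates at n = 5 000 (bias), 200 cohorts × 200 bootstrap
replicates at n = 2 000 (coverage), and 100 replicates at n = 5 000
(optimizer recovery). The acceptance script uses 100-replicate versions of
the same designs plus a 10⁶-subject reference simulation for the oracle;
these sizes give Monte-Carlo standard errors an order of magnitude below
the effects being measured.

## Known limitations

Only two risk strata and deterministic rules; no inverse-probability or
doubly robust estimators (g-computation only); no censoring or
time-varying treatment; no quantitative bias analysis for unmeasured
confounding; the bootstrap does not re-run rule optimization inside
replicates (unnecessary under the split-sample design, which is why the
split is the default workflow).
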