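"""Split-sample orchestration: train the prognostic model, optimize the
decision rule, and validate it in an emulated trial — on disjoint data.

The development/evaluation process has three steps: (1) fit the prognostic
model, (2) choose the cutoff and the utility-optimal rule, (3) emulate the
target trial to estimate the rule's clinical utility. Because steps 1-2 are
data driven, step 3 must run on data they never touched; in a data-rich
register the cohort is randomly split three ways. When the prognostic model
is external information only a two-way split (optimize / validate) is
needed, and when the whole rule is external the full cohort can serve as
the validation sample.

``run_pipeline`` wires the stages together from a single configuration
mapping (YAML on disk or a dict), logs every stage's seed and exclusion
counts, and emits a machine-readable result plus a human-readable report.
The validation partition is handed exclusively to the final stage — the
stage functions are module-level so tests can trace which partition each
one receives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import emulate, inference, prognostic, rules, synthetic_cohort
from .errors import ConfigurationError, RuleTrialError

logger = logging.getLogger(__name__)

_MODES = ("three-way", "two-way-model-given", "validate-only")
# historical alias for the two-way split with an externally supplied model
_MODE_ALIASES = {"two-way-rule-given": "two-way-model-given"}


@dataclass
class SplitPlan:
    """Random split of the cohort into (train, optimize, validate) fractions.

    A fraction may be 0 only when that stage is supplied externally, as
    declared by ``mode``. Remainder rows after floor-rounding go to the
    validation sample.
    """

    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0
    mode: str = "three-way"

    def __post_init__(self):
        self.mode = _MODE_ALIASES.get(self.mode, self.mode)
        if self.mode not in _MODES:
            raise ConfigurationError(f"unknown split mode {self.mode!r}; use {_MODES}")
        f = tuple(float(x) for x in self.fractions)
        if len(f) != 3 or any(x < 0 for x in f):
            raise ConfigurationError("fractions must be three non-negative numbers")
        if abs(sum(f) - 1.0) > 1e-12:
            raise ConfigurationError(f"fractions must sum to 1, got {sum(f)}")
        must_be_zero = {
            "three-way": (),
            "two-way-model-given": (0,),
            "validate-only": (0, 1),
        }[self.mode]
        for i in range(2):
            if i in must_be_zero and f[i] != 0.0:
                raise ConfigurationError(
                    f"mode {self.mode!r} requires fraction {i} (train/optimize) to be 0"
                )
            if i not in must_be_zero and f[i] == 0.0:
                raise ConfigurationError(
                    f"mode {self.mode!r} requires a non-zero fraction at position {i}"
                )
        self.fractions = f


def split_sample(
    cohort: pd.DataFrame, plan: SplitPlan
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive (train, optimize, validate) partition by seeded
    permutation; sizes floor-rounded with the remainder going to validate."""
    if len(cohort) == 0:
        raise ConfigurationError("cannot split an empty cohort")
    n = len(cohort)
    perm = np.random.default_rng(plan.seed).permutation(n)
    n_train = int(np.floor(plan.fractions[0] * n))
    n_opt = int(np.floor(plan.fractions[1] * n))
    parts = (
        cohort.iloc[perm[:n_train]].reset_index(drop=True),
        cohort.iloc[perm[n_train : n_train + n_opt]].reset_index(drop=True),
        cohort.iloc[perm[n_train + n_opt :]].reset_index(drop=True),
    )
    logger.info(
        "split (seed %d): train=%d optimize=%d validate=%d",
        plan.seed, len(parts[0]), len(parts[1]), len(parts[2]),
    )
    return parts


@dataclass
class PipelineResult:
    result: emulate.EmulationResult
    rule: rules.DecisionRule
    risk_model: prognostic.RiskModel
    score_table: pd.DataFrame | None
    report: str
    config: dict


# ------------------------------------------------------------------- stages

def stage_train(train: pd.DataFrame, covariates: Sequence[str]) -> prognostic.RiskModel:
    """Step 1: fit the prognostic risk model on the training sample."""
    return prognostic.fit_risk_model(train, covariates)


def stage_optimize(
    optimize: pd.DataFrame,
    risk_model: prognostic.RiskModel,
    config: Mapping,
    eligibility: emulate.EligibilitySpec,
    q_spec: emulate.QModelSpec,
    space: rules.ActionSpace,
) -> tuple[rules.DecisionRule, pd.DataFrame]:
    """Step 2: choose the cutoff(s) and the utility-optimal rule on the
    optimization sample."""
    rule_cfg = dict(config.get("rule", {}))
    risks = prognostic.predict_risk(risk_model, optimize)
    if "cutoff_grid" in rule_cfg:
        grid = [float(c) for c in rule_cfg["cutoff_grid"]]
    else:
        curve = prognostic.predictiveness_curve(
            risks, np.asarray(optimize[synthetic_cohort.OUTCOME])
        )
        crit_cfg = rule_cfg.get("cutoff", {"criterion": "high_risk_fraction", "value": 0.5})
        criterion = prognostic.CutoffCriterion(
            crit_cfg["criterion"], float(crit_cfg["value"])
        )
        grid = [prognostic.select_cutoff(curve, criterion)]
    constraints = rules.RuleConstraint(
        frozenset((s, t) for s, t in rule_cfg.get("constraints", []))
    )
    candidates = rules.enumerate_rules(space, grid, constraints)
    utility = rules.UtilitySpec(treatment_costs=rule_cfg.get("treatment_costs", {}))
    best, table = rules.optimize_rule(
        candidates, optimize, risks, q_spec, utility, eligibility
    )
    logger.info("selected rule: %s", best.describe())
    return best, table


def stage_validate(
    validate: pd.DataFrame,
    risk_model: prognostic.RiskModel,
    rule: rules.DecisionRule,
    eligibility: emulate.EligibilitySpec,
    q_spec: emulate.QModelSpec,
    space: rules.ActionSpace,
    n_boot: int,
    level: float,
    seed: int,
) -> emulate.EmulationResult:
    """Step 3: emulate the target trial on the untouched validation sample."""
    risks = prognostic.predict_risk(risk_model, validate)
    result = emulate.estimate_delta(
        validate, risks, rule, q_spec, eligibility, action_space=space.treatments
    )
    result.bootstrap = inference.bootstrap_delta(
        validate, risks, rule, q_spec, eligibility,
        n_boot=n_boot, seed=seed, level=level, action_space=space.treatments,
    )
    return result


# ------------------------------------------------------------------ pipeline

def _sub_seed(seed: int, index: int) -> int:
    """Deterministic stage seed derived from the run seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(source: str | Path | Mapping) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _eligibility_from_config(config: Mapping) -> emulate.EligibilitySpec:
    cfg = config.get("eligibility", {})
    criteria = [(c["name"], c["expr"]) for c in cfg.get("criteria", [])]
    return emulate.EligibilitySpec(
        criteria=criteria,
        grace_period_days=int(cfg.get("grace_period_days", 14)),
        horizon_days=int(cfg.get("horizon_days", 1826)),
    )


def run_pipeline(
    config: str | Path | Mapping,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline from a configuration mapping or YAML file:
    simulate-or-load -> eligibility -> split -> fit risk model (train) ->
    cutoff + rule optimization (optimize) -> emulated trial with bootstrap
    (validate) -> result + report.

    ``seed`` overrides the config seed; every stage derives its own seed
    from it. On error, partial outputs written so far remain in ``out_dir``.
    """
    config = load_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    run_seed = int(config.get("seed", 0))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "load-data"
    try:
        data_cfg = config.get("data", {})
        if "simulate" in data_cfg:
            sim_cfg = dict(data_cfg["simulate"])
            sim_cfg.setdefault("seed", _sub_seed(run_seed, 0))
            sim = synthetic_cohort.SimulationConfig.from_dict(sim_cfg)
            cohort, _ = synthetic_cohort.simulate_cohort(sim)
            logger.info("simulated cohort of %d subjects (seed %d)", len(cohort), sim.seed)
        elif "cohort_csv" in data_cfg:
            cohort = synthetic_cohort.read_cohort(data_cfg["cohort_csv"])
            logger.info("loaded cohort of %d subjects from %s",
                        len(cohort), data_cfg["cohort_csv"])
        else:
            raise ConfigurationError("config.data needs 'simulate' or 'cohort_csv'")

        space = rules.ActionSpace(tuple(config.get("action_space", ("A", "B"))))
        synthetic_cohort.validate_cohort(cohort, treatments=space.treatments)

        stage = "eligibility"
        eligibility = _eligibility_from_config(config)
        eligible = emulate.apply_eligibility(cohort, eligibility)

        stage = "split"
        split_cfg = config.get("split", {})
        plan = SplitPlan(
            fractions=tuple(split_cfg.get("fractions", (1 / 3, 1 / 3, 1 / 3))),
            seed=_sub_seed(run_seed, 1),
            mode=split_cfg.get("mode", "three-way"),
        )
        train, optimize, validate = split_sample(eligible, plan)

        q_cfg = config.get("q_model", {})
        q_spec = emulate.QModelSpec(
            covariate_names=list(q_cfg.get("covariates", [])),
            treatment_covariate_interactions=list(q_cfg.get("interactions", [])),
        )

        stage = "train-risk-model"
        rm_cfg = config.get("risk_model", {})
        if "external_file" in rm_cfg:
            risk_model = prognostic.read_risk_model(rm_cfg["external_file"])
            logger.info("risk model supplied externally from %s", rm_cfg["external_file"])
        else:
            if plan.mode != "three-way":
                raise ConfigurationError(
                    f"mode {plan.mode!r} requires an external risk model"
                )
            risk_model = stage_train(train, rm_cfg.get("covariates", []))
        if out is not None:
            prognostic.write_risk_model(risk_model, out / "risk_model.yaml")

        stage = "optimize-rule"
        score_table = None
        rule_cfg = config.get("rule", {})
        if "external_file" in rule_cfg:
            rule = rules.read_rule(rule_cfg["external_file"])
            logger.info("decision rule supplied externally from %s",
                        rule_cfg["external_file"])
        else:
            if plan.mode == "validate-only":
                raise ConfigurationError("validate-only mode requires an external rule")
            rule, score_table = stage_optimize(
                optimize, risk_model, config, eligibility, q_spec, space
            )
            if out is not None:
                rules.write_score_table(score_table, out / "rule_scores.csv")
        if out is not None:
            rules.write_rule(rule, out / "rule.yaml")

        stage = "validate"
        boot_cfg = config.get("bootstrap", {})
        result = stage_validate(
            validate, risk_model, rule, eligibility, q_spec, space,
            n_boot=int(boot_cfg.get("n_boot", 500)),
            level=float(boot_cfg.get("level", 0.95)),
            seed=_sub_seed(run_seed, 2),
        )
    except RuleTrialError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    report = render_report(config, plan, eligible, risk_model, rule, result)
    if out is not None:
        with open(out / "result.yaml", "w") as fh:
            yaml.safe_dump(result.to_dict(), fh, sort_keys=False)
        (out / "report.txt").write_text(report)
        if result.bootstrap is not None:
            result.bootstrap.dump_replicates(out / "bootstrap_replicates.csv")
    return PipelineResult(result, rule, risk_model, score_table, report, config)


def render_report(
    config: Mapping,
    plan: SplitPlan,
    eligible: pd.DataFrame,
    risk_model: prognostic.RiskModel,
    rule: rules.DecisionRule,
    result: emulate.EmulationResult,
) -> str:
    """Human-readable run summary; every default is printed so the run is
    self-documenting."""
    lines = [
        "Emulated target trial: prediction-based decision rule vs standard of care",
        "=" * 74,
        f"run seed: {config.get('seed', 0)}",
        f"split mode: {plan.mode}; fractions: {plan.fractions}",
        f"eligible subjects: {len(eligible)}",
        f"eligibility exclusions: {eligible.attrs.get('eligibility_exclusions', {})}",
        "",
        f"prognostic model ({risk_model.provenance}):",
    ]
    coefs = dict(
        zip(("(intercept)",) + risk_model.covariate_names, risk_model.coefficients)
    )
    lines += [f"  {k}: {v:+.4f}" for k, v in coefs.items()]
    lines += [
        "",
        f"decision rule: {rule.describe()}",
        "",
        "emulated trial estimates:",
        f"  n eligible (validation): {result.n_eligible}"
        f"  [low: {result.n_low}, high: {result.n_high}, early events: {result.n_early}]",
        f"  stratum weights: low {result.stratum_weights['low']:.3f}, "
        f"high {result.stratum_weights['high']:.3f}",
        f"  rule-arm mean     E[Y^pred] = {result.mean_pred_arm:.4f}",
        f"  standard-of-care  E[Y^soc]  = {result.mean_soc_arm:.4f}",
        f"  delta (ITT contrast)        = {result.delta:+.4f}",
    ]
    if result.bootstrap is not None:
        b = result.bootstrap
        lines.append(
            f"  {100 * b.level:.0f}% percentile CI: [{b.ci_lower:+.4f}, {b.ci_upper:+.4f}] "
            f"({b.n_boot} replicates, {b.n_failed} failed)"
        )
    if result.positivity_report is not None:
        pr = result.positivity_report
        lines += [
            "",
            f"positivity: {len(pr.hard_flags)} hard flag(s), {len(pr.flags)} sparse cell(s)",
        ]
        lines += [f"  HARD: {msg}" for msg in pr.hard_flags]
        lines += [f"  sparse: {msg}" for msg in pr.flags[:10]]
        if len(pr.flags) > 10:
            lines.append(f"  ... {len(pr.flags) - 10} more sparse cells")
    lines.append("")
    return "\n".join(lines)
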