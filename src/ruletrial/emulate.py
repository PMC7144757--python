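"""Emulation of the target trial comparing a prediction-based decision rule
with standard of care.

The hypothetical trial randomizes newly diagnosed, eligible patients between
(i) treating according to the decision rule applied to their prognostic risk
and (ii) the standard of care. Its intention-to-treat estimand is

    delta = E[Y^pred] - E[Y^soc],

the difference in event proportions within the horizon. In observational
data neither arm exists, so both are reconstructed:

* Standard of care *is* the observed eligible population, so ``E[Y^soc]`` is
  the plain event proportion — no modelling, no extra assumptions.
* The rule arm decomposes over the risk strata the rule induces:
  ``P(low) E[Y^a_low | low] + P(high) E[Y^a_high | high]``, where ``a_s`` is
  the treatment the rule assigns to stratum ``s``. Each stratum mean is a
  conditional potential-outcome mean, estimated by g-computation: within the
  stratum, fit the Q model (outcome regression on treatment and measured
  confounders), predict every subject's outcome with treatment set to the
  rule's assignment, and average the predictions.

Identification requires positivity of treatment assignment within every
covariate subgroup of each stratum, no unmeasured confounding, and a
correctly specified Q model; :func:`check_positivity` diagnoses the first
assumption, the other two are untestable in the data.

Time zero is diagnosis (all offsets in the cohort are relative to it).
Treatment may start within a grace period after time zero; to avoid the
survivor bias this window induces, subjects whose event occurs within the
grace period are counted in BOTH arms with their factual outcome (Y = 1),
bypassing the Q model, and are excluded from Q-model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import fit_logistic
from .errors import (
    AlignmentError,
    ConfigurationError,
    DataError,
    EstimationError,
    FittingError,
    PositivityError,
    SchemaError,
)
from .rules import HIGH, LOW, DecisionRule
from .synthetic_cohort import EVENT_OFFSET, OUTCOME, TREATMENT

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- eligibility

@dataclass
class EligibilitySpec:
    """Trial eligibility plus the follow-up frame.

    ``criteria`` is a list of (name, predicate) pairs; a predicate is either
    a pandas ``eval`` expression string over cohort columns (e.g.
    ``"age >= 18"``) or a callable mapping the cohort frame to a boolean
    mask. ``grace_period_days`` is the window after time zero within which
    treatment must start; ``horizon_days`` the outcome horizon.
    """

    criteria: list[tuple[str, str | Callable[[pd.DataFrame], pd.Series]]] = field(
        default_factory=list
    )
    grace_period_days: int = 14
    horizon_days: int = 1826

    def __post_init__(self):
        if self.grace_period_days < 0:
            raise ConfigurationError("grace_period_days must be non-negative")
        if self.grace_period_days >= self.horizon_days:
            raise ConfigurationError("grace_period_days must be < horizon_days")


def apply_eligibility(cohort: pd.DataFrame, spec: EligibilitySpec) -> pd.DataFrame:
    """Drop rows failing any eligibility predicate.

    Per-criterion exclusion counts are logged and attached to the returned
    frame as ``.attrs['eligibility_exclusions']``. A cohort where every row
    is excluded is returned empty with a warning — downstream estimators
    raise on it.
    """
    kept = cohort
    exclusions: dict[str, int] = {}
    for name, predicate in spec.criteria:
        try:
            if callable(predicate):
                mask = np.asarray(predicate(kept), dtype=bool)
            else:
                mask = np.asarray(kept.eval(predicate), dtype=bool)
        except (KeyError, pd.errors.UndefinedVariableError) as exc:
            raise SchemaError(
                f"eligibility criterion {name!r} references a missing column: {exc}"
            ) from exc
        exclusions[name] = int((~mask).sum())
        kept = kept[mask]
        logger.info("eligibility %r excluded %d rows (%d remain)",
                    name, exclusions[name], len(kept))
    if len(kept) == 0 and len(cohort) > 0:
        logger.warning("eligibility criteria excluded the entire cohort")
    kept = kept.copy()
    kept.attrs["eligibility_exclusions"] = exclusions
    return kept


def _early_event_mask(cohort: pd.DataFrame, spec: EligibilitySpec) -> np.ndarray:
    """Positional boolean mask of subjects with an event within the grace
    period (boundary inclusive)."""
    offsets = cohort[EVENT_OFFSET]
    events = (cohort[OUTCOME] == 1).to_numpy()
    if (offsets[events].dropna() < 0).any():
        raise DataError("negative event offsets")
    within = (offsets <= spec.grace_period_days).fillna(False).to_numpy(dtype=bool)
    return events & within


def grace_period_partition(
    cohort: pd.DataFrame, spec: EligibilitySpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the eligible cohort into early-event subjects (event within the
    grace period, boundary inclusive) and everyone else.

    The two sets partition the cohort. Early-event subjects are counted in
    both arms downstream, regardless of treatment.
    """
    early_mask = _early_event_mask(cohort, spec)
    return cohort[early_mask], cohort[~early_mask]


# ------------------------------------------------------------------ Q model

@dataclass
class QModelSpec:
    """Specification of the per-stratum outcome regression Q(T, X).

    Always contains a treatment main effect; ``covariate_names`` are the
    measured confounders (entered linearly); ``treatment_covariate_interactions``
    optionally adds treatment-by-covariate product terms.
    """

    covariate_names: list[str] = field(default_factory=list)
    treatment_covariate_interactions: list[str] = field(default_factory=list)

    def __post_init__(self):
        extra = set(self.treatment_covariate_interactions) - set(self.covariate_names)
        if extra:
            raise ConfigurationError(
                f"interaction covariates {sorted(extra)} are not in covariate_names"
            )


@dataclass
class QModel:
    """Fitted per-stratum outcome regression.

    ``treatment_levels`` orders the observed treatments; the first is the
    reference level, each other level gets an indicator (plus configured
    interactions). ``constant_outcome`` short-circuits fitting when the
    subgroup's outcomes have no variation — the MLE is then the constant,
    whatever the treatment.
    """

    spec: QModelSpec
    treatment_levels: tuple[str, ...]
    column_names: list[str]
    coefficients: np.ndarray | None
    constant_outcome: float | None = None
    stratum: str = ""
    # covariates that vary within the fitting subgroup; a covariate constant
    # within a stratum cannot confound there and is absorbed by the intercept
    active_covariates: tuple[str, ...] = ()
    active_interactions: tuple[str, ...] = ()

    def _design(self, subgroup: pd.DataFrame, treatments: np.ndarray) -> np.ndarray:
        n = len(subgroup)
        cols = [np.ones(n)]
        for level in self.treatment_levels[1:]:
            cols.append((treatments == level).astype(float))
        for c in self.active_covariates:
            cols.append(np.asarray(subgroup[c], dtype=float))
        for level in self.treatment_levels[1:]:
            ind = (treatments == level).astype(float)
            for c in self.active_interactions:
                cols.append(ind * np.asarray(subgroup[c], dtype=float))
        return np.column_stack(cols)

    def predict(self, subgroup: pd.DataFrame, set_treatment) -> np.ndarray:
        """Predicted event probability with treatment forced to
        ``set_treatment`` (a label, or a per-subject vector of labels)."""
        if self.constant_outcome is not None:
            return np.full(len(subgroup), self.constant_outcome)
        if np.isscalar(set_treatment) or isinstance(set_treatment, str):
            treatments = np.full(len(subgroup), set_treatment)
        else:
            treatments = np.asarray(set_treatment)
            if len(treatments) != len(subgroup):
                raise AlignmentError("set_treatment vector not aligned with subgroup")
        unknown = set(np.unique(treatments)) - set(self.treatment_levels)
        if unknown:
            raise ConfigurationError(
                f"treatment(s) {sorted(unknown)} not seen when the Q model was fitted"
            )
        return expit(self._design(subgroup, treatments) @ self.coefficients)


def fit_q_model(
    subgroup: pd.DataFrame, q_spec: QModelSpec, stratum: str = ""
) -> QModel:
    """Fit the Q model by maximum likelihood within one risk stratum.

    Requires at least two observed treatments (within-stratum positivity)
    and both outcome classes; violations raise :class:`PositivityError` /
    :class:`FittingError` naming the stratum.
    """
    missing = [c for c in q_spec.covariate_names if c not in subgroup.columns]
    if missing:
        raise SchemaError(f"subgroup lacks confounder columns {missing}")
    treatments = np.asarray(subgroup[TREATMENT])
    levels = tuple(sorted(set(treatments)))
    label = f" in stratum {stratum!r}" if stratum else ""
    if len(levels) < 2:
        raise PositivityError(
            f"only treatment {levels} observed{label}; cannot identify the "
            "treatment effect", stratum=stratum or None,
        )
    y = np.asarray(subgroup[OUTCOME], dtype=float)
    if y.min() == y.max():
        raise FittingError(f"outcome constant{label}; Q model unidentifiable")
    active_cov = tuple(
        c for c in q_spec.covariate_names
        if np.unique(np.asarray(subgroup[c], dtype=float)).size > 1
    )
    dropped = [c for c in q_spec.covariate_names if c not in active_cov]
    if dropped:
        logger.debug("Q model%s: dropping within-stratum-constant covariates %s",
                     label, dropped)
    active_int = tuple(
        c for c in q_spec.treatment_covariate_interactions if c in active_cov
    )
    model = QModel(
        q_spec, levels, [], None, stratum=stratum,
        active_covariates=active_cov, active_interactions=active_int,
    )
    X = model._design(subgroup, treatments)
    names = (
        ["(intercept)"]
        + [f"treat[{t}]" for t in levels[1:]]
        + list(active_cov)
        + [f"treat[{t}]:{c}" for t in levels[1:] for c in active_int]
    )
    try:
        model.coefficients = fit_logistic(y, X, names)
    except FittingError as exc:
        raise FittingError(f"Q model{label}: {exc}") from exc
    model.column_names = names
    return model


def _constant_q_model(q_spec: QModelSpec, value: float, stratum: str) -> QModel:
    return QModel(q_spec, (), [], None, constant_outcome=value, stratum=stratum)


def _fit_stratum_q(
    fit_rows: pd.DataFrame, q_spec: QModelSpec, stratum: str, needed: set[str]
) -> QModel:
    """Fit the Q model for one stratum, handling two degenerate-but-identified
    cases the public :func:`fit_q_model` contract rejects:

    * constant outcome in the fitting subset — the MLE is that constant
      whatever the treatment;
    * a single observed treatment that is exactly the one the rule assigns —
      no counterfactual is needed, so the regression drops the treatment
      term and becomes outcome-on-covariates.
    """
    if len(fit_rows) == 0:
        raise PositivityError(
            f"no subjects available to fit the Q model in stratum {stratum!r}",
            stratum=stratum,
        )
    y = np.asarray(fit_rows[OUTCOME], dtype=float)
    if y.min() == y.max():
        return _constant_q_model(q_spec, float(y[0]), stratum)
    observed = set(fit_rows[TREATMENT])
    if not needed <= observed:
        raise PositivityError(
            f"treatment(s) {sorted(needed - observed)} assigned by the rule are "
            f"unobserved in stratum {stratum!r}",
            stratum=stratum,
        )
    if len(observed) == 1:
        active_cov = tuple(
            c for c in q_spec.covariate_names
            if np.unique(np.asarray(fit_rows[c], dtype=float)).size > 1
        )
        model = QModel(
            q_spec, tuple(observed), [], None, stratum=stratum,
            active_covariates=active_cov,
            active_interactions=(),
        )
        X = model._design(fit_rows, np.asarray(fit_rows[TREATMENT]))
        names = ["(intercept)"] + list(active_cov)
        try:
            model.coefficients = fit_logistic(y, X, names)
        except FittingError as exc:
            raise FittingError(f"Q model in stratum {stratum!r}: {exc}") from exc
        model.column_names = names
        return model
    return fit_q_model(fit_rows, q_spec, stratum=stratum)


def gcomp_mean(qmodel: QModel, subgroup: pd.DataFrame, set_treatment) -> float:
    """g-computation estimate of the stratum potential-outcome mean: predict
    each subject's outcome with treatment set to ``set_treatment`` and their
    own covariates, then average."""
    if len(subgroup) == 0:
        raise EstimationError("cannot standardize over an empty subgroup")
    return float(np.mean(qmodel.predict(subgroup, set_treatment)))


# ------------------------------------------------------------- rule-arm mean

@dataclass
class StratumComponent:
    """One risk stratum's contribution to the rule-arm mean."""

    stratum: str
    n: int  # all eligible subjects in the stratum (early events included)
    n_early: int
    weight: float  # n / n_eligible
    assigned: str  # rule-assigned treatment ('factual' for FactualTreatmentRule)
    mean: float  # combined stratum mean: early factual 1s + g-comp predictions


@dataclass
class RuleArmDecomposition:
    mean: float
    components: list[StratumComponent]
    n_eligible: int
    n_early: int


def _strata_masks(risks: np.ndarray, cutoff: float) -> dict[str, np.ndarray]:
    high = risks >= cutoff
    return {LOW: ~high, HIGH: high}


def estimate_rule_mean(
    cohort: pd.DataFrame,
    risks: Sequence[float],
    rule: DecisionRule,
    q_spec: QModelSpec,
    spec: EligibilitySpec,
    action_space: Sequence[str] = ("A", "B"),
) -> tuple[float, RuleArmDecomposition]:
    """Estimate the rule-arm mean E[Y^pred] on an eligible cohort.

    Strata are formed by risk vs. the rule's cutoff over the whole eligible
    cohort, so the stratum weights sum to one. Within each stratum the mean
    combines (i) early-event subjects, who contribute their factual Y = 1
    directly, and (ii) everyone else via the Q model fitted on that
    stratum's non-early subjects, predicted at the rule-assigned treatment.

    Subjects whose factual treatment lies outside the action space are kept
    in the stratum (they receive a g-computation prediction) but are
    excluded from Q-model fitting.
    """
    risks = np.asarray(risks, dtype=float)
    if len(risks) != len(cohort):
        raise AlignmentError(
            f"risks ({len(risks)}) and cohort ({len(cohort)}) must be aligned"
        )
    if len(cohort) == 0:
        raise EstimationError("empty eligible cohort")
    early_mask = _early_event_mask(cohort, spec)
    masks = _strata_masks(risks, rule.cutoff)
    assigned_all = rule.assign(risks, np.asarray(cohort[TREATMENT]))

    n = len(cohort)
    components: list[StratumComponent] = []
    total = 0.0
    for stratum, mask in masks.items():
        assigned_label = (
            rule.assignment[stratum] if hasattr(rule, "assignment") else "factual"
        )
        n_s = int(mask.sum())
        if n_s == 0:
            components.append(
                StratumComponent(stratum, 0, 0, 0.0, assigned_label, float("nan"))
            )
            continue
        early_s = mask & early_mask
        main_s = mask & ~early_mask
        n_early_s = int(early_s.sum())
        contrib = float(n_early_s)  # early events enter with factual Y = 1
        if main_s.any():
            sub = cohort[main_s]
            set_treatment = assigned_all[main_s]
            fit_rows = sub[sub[TREATMENT].isin(list(action_space))]
            needed = set(np.unique(set_treatment))
            qmodel = _fit_stratum_q(fit_rows, q_spec, stratum, needed)
            contrib += float(np.sum(qmodel.predict(sub, set_treatment)))
        mean_s = contrib / n_s
        components.append(
            StratumComponent(stratum, n_s, n_early_s, n_s / n, assigned_label, mean_s)
        )
        total += (n_s / n) * mean_s
    decomp = RuleArmDecomposition(
        mean=total,
        components=components,
        n_eligible=n,
        n_early=int(early_mask.sum()),
    )
    return total, decomp


def estimate_soc_mean(cohort: pd.DataFrame, spec: EligibilitySpec) -> float:
    """Standard-of-care arm mean: the event proportion over ALL eligible
    subjects, regardless of treatment (early events included — they sit in
    both arms)."""
    if len(cohort) == 0:
        raise EstimationError("empty eligible cohort")
    return float(np.mean(cohort[OUTCOME]))


# ------------------------------------------------------------------ delta

@dataclass
class EmulationResult:
    """Point estimates from one emulated trial.

    ``delta = mean_pred_arm - mean_soc_arm`` is the intention-to-treat
    contrast; negative values favour the decision rule (fewer events).
    """

    mean_pred_arm: float
    mean_soc_arm: float
    delta: float
    stratum_weights: dict[str, float]
    stratum_potential_means: dict[str, float]
    stratum_assigned: dict[str, str]
    n_eligible: int
    n_low: int
    n_high: int
    n_early: int
    positivity_report: "PositivityReport | None" = None
    bootstrap: object | None = None  # BootstrapResult, attached by workflow

    def to_dict(self) -> dict:
        d = {
            "mean_pred_arm": self.mean_pred_arm,
            "mean_soc_arm": self.mean_soc_arm,
            "delta": self.delta,
            "stratum_weights": self.stratum_weights,
            "stratum_potential_means": self.stratum_potential_means,
            "stratum_assigned": self.stratum_assigned,
            "n_eligible": self.n_eligible,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "n_early": self.n_early,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = {
                "ci_lower": self.bootstrap.ci_lower,
                "ci_upper": self.bootstrap.ci_upper,
                "n_boot": self.bootstrap.n_boot,
                "n_failed": self.bootstrap.n_failed,
                "level": self.bootstrap.level,
            }
        return d


def estimate_delta(
    cohort: pd.DataFrame,
    risks: Sequence[float],
    rule: DecisionRule,
    q_spec: QModelSpec,
    spec: EligibilitySpec,
    action_space: Sequence[str] = ("A", "B"),
    compute_positivity: bool = True,
) -> EmulationResult:
    """Full emulated-trial point estimate: both arm means and their contrast.

    Every eligible subject contributes to the standard-of-care mean; the
    same subjects, stratified by risk, contribute to the rule-arm mean — the
    two arms share subjects, which is why interval estimation resamples
    whole subjects (see :mod:`ruletrial.inference`).
    """
    pred_mean, decomp = estimate_rule_mean(
        cohort, risks, rule, q_spec, spec, action_space=action_space
    )
    soc_mean = estimate_soc_mean(cohort, spec)
    by_stratum = {c.stratum: c for c in decomp.components}
    report = (
        check_positivity(cohort, risks, rule, q_spec) if compute_positivity else None
    )
    return EmulationResult(
        mean_pred_arm=pred_mean,
        mean_soc_arm=soc_mean,
        delta=pred_mean - soc_mean,
        stratum_weights={s: by_stratum[s].weight for s in (LOW, HIGH)},
        stratum_potential_means={s: by_stratum[s].mean for s in (LOW, HIGH)},
        stratum_assigned={s: by_stratum[s].assigned for s in (LOW, HIGH)},
        n_eligible=decomp.n_eligible,
        n_low=by_stratum[LOW].n,
        n_high=by_stratum[HIGH].n,
        n_early=decomp.n_early,
        positivity_report=report,
    )


# ----------------------------------------------------------------- positivity

@dataclass
class PositivityCell:
    stratum: str
    covariate: str
    cell: str
    n_cell: int
    n_assigned_treatment: int
    flagged: bool


@dataclass
class PositivityReport:
    """Diagnostic counts of rule-assigned treatment per covariate cell.

    ``hard_flags`` lists strata where NOBODY received the treatment the rule
    assigns — g-computation is then unidentified in that stratum.
    ``flags`` lists covariate cells whose assigned-treatment count falls
    below the floor (sparse-data warning, not an error).
    """

    cells: list[PositivityCell]
    flags: list[str]
    hard_flags: list[str]
    stratum_sizes: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.hard_flags


_MAX_DISCRETE_LEVELS = 10


def check_positivity(
    cohort: pd.DataFrame,
    risks: Sequence[float],
    rule: DecisionRule,
    q_spec: QModelSpec,
    floor: int = 5,
) -> PositivityReport:
    """Count, per stratum and covariate cell, subjects who factually received
    the rule-assigned treatment. Purely diagnostic — never raises.

    Covariates with more than 10 distinct values are decile-binned; empty
    strata are reported with size 0 and not flagged.
    """
    risks = np.asarray(risks, dtype=float)
    masks = _strata_masks(risks, rule.cutoff)
    treatments = np.asarray(cohort[TREATMENT])
    assigned_all = rule.assign(risks, treatments)
    cells: list[PositivityCell] = []
    flags: list[str] = []
    hard_flags: list[str] = []
    sizes: dict[str, int] = {}
    for stratum, mask in masks.items():
        n_s = int(mask.sum())
        sizes[stratum] = n_s
        if n_s == 0:
            continue
        got_assigned = treatments[mask] == assigned_all[mask]
        if not got_assigned.any():
            hard_flags.append(
                f"stratum {stratum!r} (n={n_s}): nobody received the assigned treatment"
            )
        sub = cohort[mask]
        for cov in q_spec.covariate_names:
            values = pd.Series(np.asarray(sub[cov]))
            if values.nunique() > _MAX_DISCRETE_LEVELS:
                binned = pd.qcut(values, 10, duplicates="drop").astype(str)
            else:
                binned = values.astype(str)
            for cell_label in binned.unique():
                in_cell = (binned == cell_label).to_numpy()
                n_cell = int(in_cell.sum())
                n_treat = int((in_cell & got_assigned).sum())
                flagged = n_treat < floor
                cells.append(
                    PositivityCell(stratum, cov, str(cell_label), n_cell, n_treat, flagged)
                )
                if flagged:
                    flags.append(
                        f"stratum {stratum!r}, {cov}={cell_label}: only {n_treat} "
                        f"of {n_cell} received the assigned treatment (floor {floor})"
                    )
    return PositivityReport(cells, flags, hard_flags, sizes)
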