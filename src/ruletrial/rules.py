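"""Action spaces, prediction-based decision rules, and rule optimization.

A decision rule here is deterministic and one-dimensional: a cutoff on the
prognostic risk score splits subjects into a low- and a high-risk stratum,
and each stratum is mapped to one treatment from the action space (default:
``A`` = monotherapy, ``B`` = combination therapy). "High risk" means
``risk >= cutoff`` — the boundary is closed on the high side, a convention
fixed package-wide.

Expert-opinion constraints (e.g. "combination therapy must not be given to
low-risk patients") are expressed as forbidden (stratum, treatment) pairs and
pruned from the enumerated candidate set before optimization.

Rule optimization scores every admissible candidate with the same
g-computation estimator used for validation, through a pluggable scalar
utility (default: the estimated event proportion itself, minimized), and
returns the argmin. Ties break toward the larger cutoff — the rule that
escalates fewer patients — then lexicographically on the assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FittingError, OptimizationError, PositivityError

logger = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"


@dataclass(frozen=True)
class ActionSpace:
    """Ordered set of treatment labels a rule may assign."""

    treatments: tuple[str, ...] = ("A", "B")

    def __post_init__(self):
        if len(set(self.treatments)) < 2:
            raise ConfigurationError("action space needs >= 2 distinct treatments")

    def __contains__(self, label: str) -> bool:
        return label in self.treatments


DEFAULT_ACTION_SPACE = ActionSpace()


@dataclass(frozen=True)
class DecisionRule:
    """Risk cutoff plus a {low, high} stratum -> treatment mapping."""

    cutoff: float
    low: str
    high: str

    def __post_init__(self):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ConfigurationError(f"cutoff must be in [0, 1], got {self.cutoff}")

    @property
    def assignment(self) -> dict[str, str]:
        return {LOW: self.low, HIGH: self.high}

    def is_constant(self) -> bool:
        return self.low == self.high

    def assign(self, risks: np.ndarray, observed_treatments=None) -> np.ndarray:
        """Treatment label per subject; observed treatments are ignored."""
        risks = np.asarray(risks, dtype=float)
        return np.where(risks >= self.cutoff, self.high, self.low)

    def describe(self) -> str:
        if self.is_constant():
            return f"treat everyone with {self.low}"
        return f"risk < {self.cutoff:g} -> {self.low}; risk >= {self.cutoff:g} -> {self.high}"


@dataclass(frozen=True)
class FactualTreatmentRule:
    """Diagnostic rule that assigns every subject their factually received
    treatment. With a saturated Q model the emulated rule arm then reproduces
    the observed event proportion exactly, a useful self-check. The cutoff
    only defines the strata used for the per-stratum Q fits."""

    cutoff: float = 0.5
    low: str = "factual"
    high: str = "factual"

    def is_constant(self) -> bool:
        return False

    def assign(self, risks: np.ndarray, observed_treatments=None) -> np.ndarray:
        if observed_treatments is None:
            raise ConfigurationError(
                "FactualTreatmentRule needs the observed treatment vector"
            )
        return np.asarray(observed_treatments)

    def describe(self) -> str:
        return "assign each subject their factual treatment"


@dataclass(frozen=True)
class RuleConstraint:
    """Forbidden (stratum, treatment) pairs, e.g. {('low', 'B')}."""

    forbidden: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        for stratum, _ in self.forbidden:
            if stratum not in (LOW, HIGH):
                raise ConfigurationError(f"unknown stratum {stratum!r} in constraint")

    def allows(self, rule: DecisionRule) -> bool:
        return (LOW, rule.low) not in self.forbidden and (
            HIGH,
            rule.high,
        ) not in self.forbidden


@dataclass
class UtilitySpec:
    """Scalar clinical utility to be minimized.

    The default scores a rule by the estimated event proportion alone.
    Optional per-treatment costs add ``cost[t] * fraction assigned t`` so
    that, e.g., escalation to combination therapy can be penalized.
    """

    treatment_costs: Mapping[str, float] = field(default_factory=dict)

    def score(self, event_proportion: float, assigned_fractions: Mapping[str, float]) -> float:
        cost = sum(
            self.treatment_costs.get(t, 0.0) * frac
            for t, frac in assigned_fractions.items()
        )
        return float(event_proportion + cost)


def apply_rule(rule: DecisionRule, risks: Sequence[float]) -> np.ndarray:
    """Vector of treatment labels: ``assignment[high]`` where risk >= cutoff,
    else ``assignment[low]``."""
    risks = np.asarray(risks, dtype=float)
    if risks.size and (risks.min() < 0 or risks.max() > 1):
        raise ConfigurationError("risks must lie in [0, 1]")
    return rule.assign(risks)


def enumerate_rules(
    space: ActionSpace,
    cutoff_grid: Sequence[float],
    constraints: RuleConstraint = RuleConstraint(),
) -> list[DecisionRule]:
    """All admissible rules: cutoffs x ordered treatment pairs, minus
    constrained combinations. Constant rules ("treat everyone with t") do not
    depend on the cutoff and are kept once each, at cutoff 1.0."""
    grid = [float(c) for c in cutoff_grid]
    if not grid:
        raise ConfigurationError("cutoff grid is empty")
    if any(not 0.0 <= c <= 1.0 for c in grid):
        raise ConfigurationError("cutoffs must lie in [0, 1]")
    rules: list[DecisionRule] = []
    for cutoff in grid:
        for t_low in space.treatments:
            for t_high in space.treatments:
                if t_low == t_high:
                    continue
                rule = DecisionRule(cutoff, t_low, t_high)
                if constraints.allows(rule):
                    rules.append(rule)
    for t in space.treatments:
        rule = DecisionRule(1.0, t, t)
        if constraints.allows(rule):
            rules.append(rule)
    if not rules:
        raise OptimizationError("constraints leave no admissible rule")
    return rules


def optimize_rule(
    candidates: Sequence[DecisionRule],
    cohort: pd.DataFrame,
    risks: np.ndarray,
    q_spec,
    utility: UtilitySpec | None = None,
    eligibility=None,
    positivity_floor: int = 5,
) -> tuple[DecisionRule, pd.DataFrame]:
    """Score every candidate rule on the optimization sample and return the
    utility-optimal one plus the full score table.

    Each candidate's event proportion under the rule is estimated with the
    same per-stratum g-computation estimator used at validation
    (:func:`ruletrial.emulate.estimate_rule_mean`). Candidates whose
    rule-assigned treatment is unobserved in a non-empty stratum (hard
    positivity failure) or whose Q model cannot be fitted are flagged
    unevaluable and excluded with a logged warning.
    """
    from . import emulate  # deferred: emulate imports this module

    if not candidates:
        raise OptimizationError("no candidate rules supplied")
    utility = utility or UtilitySpec()
    if eligibility is None:
        eligibility = emulate.EligibilitySpec(grace_period_days=0)

    rows = []
    for rule in candidates:
        report = emulate.check_positivity(
            cohort, risks, rule, q_spec, floor=positivity_floor
        )
        record = {
            "cutoff": rule.cutoff,
            "low": rule.low,
            "high": rule.high,
            "evaluable": True,
            "event_proportion": np.nan,
            "utility": np.nan,
        }
        if report.hard_flags:
            logger.warning(
                "candidate %s unevaluable: %s", rule.describe(), report.hard_flags
            )
            record["evaluable"] = False
            rows.append((rule, record))
            continue
        try:
            mean, decomp = emulate.estimate_rule_mean(
                cohort, risks, rule, q_spec, eligibility
            )
        except (PositivityError, FittingError) as exc:
            logger.warning("candidate %s unevaluable: %s", rule.describe(), exc)
            record["evaluable"] = False
            rows.append((rule, record))
            continue
        assigned = rule.assign(np.asarray(risks), np.asarray(cohort[emulate.TREATMENT]))
        labels, counts = np.unique(assigned, return_counts=True)
        fractions = dict(zip(labels, counts / len(assigned)))
        record["event_proportion"] = mean
        record["utility"] = utility.score(mean, fractions)
        rows.append((rule, record))

    table = pd.DataFrame([rec for _, rec in rows])
    evaluable = [(rule, rec) for rule, rec in rows if rec["evaluable"]]
    if not evaluable:
        raise OptimizationError("every candidate rule failed positivity or fitting")
    # argmin with ties toward larger cutoff, then lexicographic assignment
    best_rule, _ = min(
        evaluable, key=lambda item: (item[1]["utility"], -item[1]["cutoff"],
                                     (item[0].low, item[0].high))
    )
    return best_rule, table


# ----------------------------------------------------------------- serialization

def write_rule(rule: DecisionRule, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"cutoff": float(rule.cutoff), "low": rule.low, "high": rule.high}, fh
        )


def read_rule(path: str | Path) -> DecisionRule:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return DecisionRule(float(d["cutoff"]), str(d["low"]), str(d["high"]))


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
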