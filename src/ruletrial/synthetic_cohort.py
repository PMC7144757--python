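"""Synthetic observational cohorts with known potential outcomes.

The simulator emulates a disease-register cohort of newly diagnosed patients
(the running example is a Crohn's-like register): baseline covariates, a
treatment received within a grace period after diagnosis (assignment depends
on covariates, so treatment is confounded), and a binary adverse outcome
(e.g. major surgery) within a fixed horizon, by default 5 years.

Because the simulator draws both potential outcomes — the outcome the subject
would have under monotherapy ``A`` and under combination therapy ``B`` — every
causal estimator in the package can be benchmarked against exact ground truth:
:func:`true_rule_value` returns the exact value a decision rule would achieve
in the simulated population.

Potential outcomes share a single uniform draw per subject, compared against
the two risk thresholds. This makes the individual treatment effect monotone
(a subject helped by ``B`` under one seed is never harmed under the same
seed) and makes the null case ``treatment_effect_B_vs_A = 0`` yield exactly
equal potential outcomes per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import AlignmentError, ConfigurationError, DataError

#: Column names of the cohort table.
ID = "id"
TREATMENT = "treatment"
TREATMENT_START = "treatment_start_offset_days"
OUTCOME = "outcome"
EVENT_OFFSET = "event_offset_days"

_FAMILIES = ("bernoulli", "normal", "uniform")

# fixed sub-stream keys: adding a covariate must not perturb the other streams
_STREAM_ASSIGNMENT = (1,)
_STREAM_OUTCOME = (2,)
_STREAM_EVENT_TIME = (3,)
_STREAM_START_TIME = (4,)


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: ``family`` is bernoulli(p), normal(mu, sd) or
    uniform(low, high); ``params`` are the family's parameters in that order."""

    name: str
    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown covariate distribution family {self.family!r}; "
                f"choose from {_FAMILIES}"
            )
        n_expected = 1 if self.family == "bernoulli" else 2
        if len(self.params) != n_expected:
            raise ConfigurationError(
                f"covariate {self.name!r}: family {self.family!r} takes "
                f"{n_expected} parameter(s), got {len(self.params)}"
            )


@dataclass
class SimulationConfig:
    """Data-generating parameters for one synthetic cohort.

    All coefficient vectors are on the log-odds scale and ordered
    (intercept, then one entry per covariate in ``covariates`` order).

    Parameters
    ----------
    n_subjects:
        Cohort size.
    covariates:
        Baseline covariate specifications.
    risk_coefficients:
        Log-odds of the event within the horizon under treatment ``A``
        (monotherapy); this is also the "true risk" the prognostic model
        targets.
    treatment_effect_B_vs_A:
        Log-odds shift applied when treated with ``B`` (combination
        therapy). Negative values mean ``B`` is protective.
    effect_modifier / effect_modifier_coefficient:
        Optional qualitative interaction: the ``B`` effect becomes
        ``treatment_effect_B_vs_A + coefficient * x`` for the named covariate.
    confounding_coefficients:
        Log-odds of receiving ``B`` given covariates; non-zero slopes create
        confounding by indication.
    grace_period_days:
        Window after diagnosis (time zero) within which treatment starts.
    horizon_days:
        Outcome horizon; default 1826 days (5 years).
    """

    n_subjects: int
    covariates: list[CovariateSpec]
    risk_coefficients: Sequence[float]
    treatment_effect_B_vs_A: float
    confounding_coefficients: Sequence[float]
    effect_modifier: str | None = None
    effect_modifier_coefficient: float = 0.0
    grace_period_days: int = 14
    horizon_days: int = 1826
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        k = len(self.covariates)
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for label, vec in (
            ("risk_coefficients", self.risk_coefficients),
            ("confounding_coefficients", self.confounding_coefficients),
        ):
            if len(vec) != k + 1:
                raise ConfigurationError(
                    f"{label} must have length 1 + n_covariates = {k + 1}, "
                    f"got {len(vec)}"
                )
        if self.grace_period_days < 0:
            raise ConfigurationError("grace_period_days must be non-negative")
        if not 0 < self.horizon_days:
            raise ConfigurationError("horizon_days must be positive")
        if self.grace_period_days >= self.horizon_days:
            raise ConfigurationError("grace_period_days must be < horizon_days")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate covariate names in {names}")
        if self.effect_modifier is not None and self.effect_modifier not in names:
            raise ConfigurationError(
                f"effect_modifier {self.effect_modifier!r} is not a covariate"
            )

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["covariates"] = [
            CovariateSpec(c["name"], c["family"], tuple(c["params"]))
            for c in d["covariates"]
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "covariates": [
                {"name": c.name, "family": c.family, "params": list(c.params)}
                for c in self.covariates
            ],
            "risk_coefficients": list(map(float, self.risk_coefficients)),
            "treatment_effect_B_vs_A": float(self.treatment_effect_B_vs_A),
            "confounding_coefficients": list(map(float, self.confounding_coefficients)),
            "effect_modifier": self.effect_modifier,
            "effect_modifier_coefficient": float(self.effect_modifier_coefficient),
            "grace_period_days": int(self.grace_period_days),
            "horizon_days": int(self.horizon_days),
            "seed": int(self.seed),
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stream(seed: int, spawn_key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _draw_covariate(spec: CovariateSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.family == "bernoulli":
        return rng.binomial(1, spec.params[0], size=n).astype(float)
    if spec.family == "normal":
        return rng.normal(spec.params[0], spec.params[1], size=n)
    return rng.uniform(spec.params[0], spec.params[1], size=n)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one observational cohort.

    Returns
    -------
    cohort:
        One row per subject: id, covariates, received treatment (``A``/``B``),
        treatment start offset from time zero, binary outcome within the
        horizon, and the event offset in days (missing when no event).
    potential:
        Ground truth aligned row-by-row with ``cohort``: ``y_under_A``,
        ``y_under_B`` and ``true_risk`` (event probability under ``A``).
    """
    config.validate()
    n = config.n_subjects
    names = [c.name for c in config.covariates]

    # one named stream per covariate so the list can grow without perturbing
    # the assignment/outcome streams
    X = np.column_stack(
        [np.ones(n)]
        + [
            _draw_covariate(spec, _stream(config.seed, (0, i)), n)
            for i, spec in enumerate(config.covariates)
        ]
    )

    eta_A = X @ np.asarray(config.risk_coefficients, dtype=float)
    effect = np.full(n, float(config.treatment_effect_B_vs_A))
    if config.effect_modifier is not None:
        xm = X[:, 1 + names.index(config.effect_modifier)]
        effect = effect + config.effect_modifier_coefficient * xm
    eta_B = eta_A + effect

    p_A = expit(eta_A)
    p_B = expit(eta_B)

    p_treat_B = expit(X @ np.asarray(config.confounding_coefficients, dtype=float))
    got_B = _stream(config.seed, _STREAM_ASSIGNMENT).uniform(size=n) < p_treat_B
    treatment = np.where(got_B, "B", "A")

    # shared uniform draw => monotone individual effects
    u = _stream(config.seed, _STREAM_OUTCOME).uniform(size=n)
    y_A = (u < p_A).astype(int)
    y_B = (u < p_B).astype(int)
    y = np.where(got_B, y_B, y_A)

    event_offsets = _stream(config.seed, _STREAM_EVENT_TIME).integers(
        1, config.horizon_days + 1, size=n
    )
    start_offsets = _stream(config.seed, _STREAM_START_TIME).integers(
        0, config.grace_period_days + 1, size=n
    )

    cohort = pd.DataFrame(
        {
            ID: [f"S{i:07d}" for i in range(n)],
            **{name: X[:, 1 + j] for j, name in enumerate(names)},
            TREATMENT: treatment,
            TREATMENT_START: start_offsets,
            OUTCOME: y,
            EVENT_OFFSET: pd.array(
                np.where(y == 1, event_offsets, -1), dtype="Int64"
            ),
        }
    )
    cohort.loc[cohort[OUTCOME] == 0, EVENT_OFFSET] = pd.NA

    potential = pd.DataFrame(
        {ID: cohort[ID], "y_under_A": y_A, "y_under_B": y_B, "true_risk": p_A}
    )
    return cohort, potential


def true_rule_value(
    potential: pd.DataFrame,
    cohort: pd.DataFrame,
    rule,
    risks: np.ndarray,
) -> float:
    """Exact population value of a decision rule: the mean of the potential
    outcome under the treatment the rule assigns to each simulated subject.

    This is the simulator-side oracle for the rule-arm mean ``E[Y^pred]``;
    it needs the potential-outcome table and is unavailable on real data.
    """
    from .rules import apply_rule

    risks = np.asarray(risks, dtype=float)
    if len(risks) != len(cohort) or len(potential) != len(cohort):
        raise AlignmentError(
            f"risks ({len(risks)}), potential ({len(potential)}) and cohort "
            f"({len(cohort)}) must be aligned"
        )
    assigned = rule.assign(risks, np.asarray(cohort[TREATMENT]))
    y_pot = np.where(
        assigned == "B",
        np.asarray(potential["y_under_B"]),
        np.asarray(potential["y_under_A"]),
    )
    return float(np.mean(y_pot))


def validate_cohort(cohort: pd.DataFrame, treatments: Sequence[str] = ("A", "B")) -> None:
    """Check the cohort-table invariants; raise :class:`DataError` on violation."""
    required = {ID, TREATMENT, OUTCOME, EVENT_OFFSET}
    missing = required - set(cohort.columns)
    if missing:
        raise DataError(f"cohort table is missing columns {sorted(missing)}")
    if cohort[ID].duplicated().any():
        raise DataError("cohort ids are not unique")
    if not cohort[OUTCOME].isin([0, 1]).all():
        raise DataError("outcome must be 0/1")
    if not cohort[TREATMENT].isin(list(treatments)).all():
        bad = sorted(set(cohort[TREATMENT]) - set(treatments))
        raise DataError(f"treatment labels {bad} outside the action space {list(treatments)}")
    events = cohort[cohort[OUTCOME] == 1]
    if events[EVENT_OFFSET].isna().any():
        raise DataError("event_offset_days missing for subjects with an event")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort as comma-delimited text; missing event offsets are empty."""
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, dtype={ID: str})
    cohort[EVENT_OFFSET] = pd.array(cohort[EVENT_OFFSET], dtype="Int64")
    return cohort


def write_potential(potential: pd.DataFrame, path: str | Path) -> None:
    potential.to_csv(path, index=False)


def read_potential(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={ID: str})
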