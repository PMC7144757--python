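"""The fixed prognostic risk model and the predictiveness curve.

The decision rule is driven by a prognostic model for the event risk within
the horizon (here: a main-effects logistic regression of the outcome on
baseline covariates). The package can fit this model on a training split or
accept externally supplied coefficients — in the intended workflow the
prognostic model is fixed before the emulated trial is run.

The predictiveness curve describes the distribution of risk in the
population: at each quantile ``q`` of the risk-score distribution it reports
the risk value at that quantile and the empirical event rate among subjects
whose risk exceeds it. It is the device used to choose the cutoff between
the low- and high-risk strata, either by targeting a fraction of the
population to classify as high risk or by fixing an absolute risk threshold.

Quantiles use linear interpolation between order statistics (the numpy
default), so e.g. the median of (0.1, 0.2, 0.3, 0.4) is 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from ._glm import check_full_rank, fit_logistic
from .errors import AlignmentError, ConfigurationError, FittingError, SchemaError
from .synthetic_cohort import OUTCOME


@dataclass(frozen=True)
class RiskModel:
    """Logistic prognostic model: P(event) = expit(b0 + b . x)."""

    covariate_names: tuple[str, ...]
    coefficients: tuple[float, ...]  # intercept first
    provenance: str = "fitted-internally"  # or "supplied-externally"

    def __post_init__(self):
        if len(self.coefficients) != 1 + len(self.covariate_names):
            raise ConfigurationError(
                f"need 1 + {len(self.covariate_names)} coefficients, "
                f"got {len(self.coefficients)}"
            )


def fit_risk_model(
    cohort: pd.DataFrame, covariate_names: Sequence[str]
) -> RiskModel:
    """Maximum-likelihood logistic regression of the outcome on the named
    baseline covariates (main effects, intercept included)."""
    missing = [c for c in covariate_names if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort lacks covariate columns {missing}")
    y = np.asarray(cohort[OUTCOME], dtype=float)
    if y.min() == y.max():
        raise FittingError("outcome has a single class; cannot fit a risk model")
    X = np.column_stack(
        [np.ones(len(cohort))] + [np.asarray(cohort[c], dtype=float) for c in covariate_names]
    )
    names = ["(intercept)"] + list(covariate_names)
    params = fit_logistic(y, X, names)
    return RiskModel(tuple(covariate_names), tuple(map(float, params)))


def predict_risk(model: RiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Predicted event probability per row: inverse-logit of the linear predictor."""
    missing = [c for c in model.covariate_names if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort lacks covariate columns {missing}")
    X = np.column_stack(
        [np.ones(len(cohort))]
        + [np.asarray(cohort[c], dtype=float) for c in model.covariate_names]
    )
    return expit(X @ np.asarray(model.coefficients))


@dataclass
class PredictivenessCurve:
    """Risk distribution summary on a quantile grid.

    ``risk_at_quantile[k]`` is the empirical risk quantile at grid point k;
    ``outcome_rate_above[k]`` is the event rate among subjects with risk
    strictly above that value (NaN when no subject lies above it).
    """

    quantile_grid: np.ndarray
    risk_at_quantile: np.ndarray
    outcome_rate_above: np.ndarray
    risks: np.ndarray = field(repr=False)  # sorted copy, for cutoff selection

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantile": self.quantile_grid,
                "risk_at_quantile": self.risk_at_quantile,
                "outcome_rate_above": self.outcome_rate_above,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def predictiveness_curve(
    risks: Sequence[float],
    outcomes: Sequence[int],
    quantile_grid: Sequence[float] | None = None,
) -> PredictivenessCurve:
    """Empirical predictiveness curve of a risk score against observed outcomes."""
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if len(risks) != len(outcomes):
        raise AlignmentError(
            f"risks ({len(risks)}) and outcomes ({len(outcomes)}) must be aligned"
        )
    if quantile_grid is None:
        quantile_grid = np.linspace(0.0, 0.95, 20)
    grid = np.asarray(quantile_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ConfigurationError("quantile grid must be strictly increasing")
    if grid.min() < 0 or grid.max() > 1:
        raise ConfigurationError("quantile grid must lie in [0, 1]")
    rq = np.quantile(risks, grid)
    rates = np.empty_like(rq)
    for k, threshold in enumerate(rq):
        above = risks > threshold
        rates[k] = outcomes[above].mean() if above.any() else np.nan
    return PredictivenessCurve(grid, rq, rates, np.sort(risks))


@dataclass(frozen=True)
class CutoffCriterion:
    """How to pick the low/high risk cutoff from the curve.

    ``kind='high_risk_fraction'``: classify the top ``value`` fraction of the
    risk distribution as high risk (cutoff = risk quantile at 1 - value).
    ``kind='risk_threshold'``: use ``value`` as an absolute risk cutoff.
    """

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("high_risk_fraction", "risk_threshold"):
            raise ConfigurationError(f"unknown cutoff criterion {self.kind!r}")


def select_cutoff(curve: PredictivenessCurve, criterion: CutoffCriterion) -> float:
    """Deterministic cutoff from the predictiveness curve."""
    if curve.risks.size == 0:
        raise ConfigurationError("cannot select a cutoff from an empty curve")
    if criterion.kind == "risk_threshold":
        return float(criterion.value)
    q = criterion.value
    if not 0.0 < q < 1.0:
        raise ConfigurationError(
            f"target high-risk fraction must be in (0, 1), got {q}"
        )
    return float(np.quantile(curve.risks, 1.0 - q))


# ----------------------------------------------------------------- serialization

def write_risk_model(model: RiskModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "covariate_names": list(model.covariate_names),
                "coefficients": list(model.coefficients),
                "provenance": model.provenance,
            },
            fh,
            sort_keys=False,
        )


def read_risk_model(path: str | Path) -> RiskModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return RiskModel(
        tuple(d["covariate_names"]),
        tuple(float(c) for c in d["coefficients"]),
        d.get("provenance", "supplied-externally"),
    )
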