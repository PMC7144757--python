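"""Internal maximum-likelihood logistic fitting shared by the prognostic
and outcome-regression (Q) models.

Thin wrapper around :class:`statsmodels.api.Logit` that adds the checks the
causal pipeline needs: rank diagnostics that name the offending columns,
separation detection, and a hard convergence guarantee (score norm below
``GRADIENT_TOL``) so toy examples with closed-form MLEs are reproduced to
numerical precision.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import FittingError

GRADIENT_TOL = 1e-8
_SEPARATION_COEF = 1e2  # |coef| beyond this on a standardized design means separation


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise :class:`FittingError` naming (approximately) collinear columns."""
    if X.shape[0] < X.shape[1]:
        raise FittingError(
            f"design has more columns ({X.shape[1]}) than rows ({X.shape[0]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank relative to the rest
        offending = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                offending.append(names[j])
        raise FittingError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {offending or names}"
        )


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str]) -> np.ndarray:
    """ML logistic regression of binary ``y`` on design ``X`` (intercept included
    by the caller). Returns the coefficient vector.

    Raises :class:`FittingError` on rank deficiency, separation, or
    non-convergence (score norm >= GRADIENT_TOL).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    check_full_rank(X, names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            # convergence is verified below via the score norm
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, X).fit(method="newton", tol=1e-12, maxiter=200, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise FittingError(f"perfect separation while fitting on columns {names}") from exc
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"singular Hessian while fitting on columns {names}") from exc
    params = np.asarray(res.params, dtype=float)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    if np.any(np.abs(params) * scale > _SEPARATION_COEF):
        raise FittingError(
            f"diverging coefficients (likely quasi-separation) on columns {names}"
        )
    p = _expit(X @ params)
    score = X.T @ (y - p)
    if not np.all(np.abs(score) < GRADIENT_TOL * max(1.0, len(y))):
        raise FittingError(
            f"logistic fit did not converge (max |score| = {np.abs(score).max():.3g})"
        )
    return params


def _expit(eta: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(eta)
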