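"""Shared fixtures: small simulation scenarios used across the test suite."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import ruletrial as rt


def confounded_config(n_subjects: int, seed: int) -> rt.SimulationConfig:
    """Confounding by indication: a binary covariate raises both the event
    risk and the probability of receiving combination therapy B, while B
    lowers the event risk. The naive treat-all-B contrast is biased by
    +0.044 (closed form); the covariate-adjusted one is consistent."""
    return rt.SimulationConfig(
        n_subjects=n_subjects,
        covariates=[rt.CovariateSpec("x", "bernoulli", (0.5,))],
        risk_coefficients=[-1.2, 1.2],
        treatment_effect_B_vs_A=-0.8,
        confounding_coefficients=[-1.0, 2.0],
        grace_period_days=14,
        horizon_days=1826,
        seed=seed,
    )


def interaction_config(n_subjects: int, seed: int) -> rt.SimulationConfig:
    """Qualitative interaction: risk under A is expit(logit(0.3) + x) with
    x ~ N(0,1), and B shifts the log-odds by -2x, so B helps exactly when
    the risk exceeds 0.3 — cutoff 0.3 is the true optimum."""
    return rt.SimulationConfig(
        n_subjects=n_subjects,
        covariates=[rt.CovariateSpec("x", "normal", (0.0, 1.0))],
        risk_coefficients=[float(logit(0.3)), 1.0],
        treatment_effect_B_vs_A=0.0,
        effect_modifier="x",
        effect_modifier_coefficient=-2.0,
        confounding_coefficients=[0.0, 0.0],
        grace_period_days=14,
        horizon_days=1826,
        seed=seed,
    )


def randomized_config(n_subjects: int, seed: int) -> rt.SimulationConfig:
    """Marginal 50/50 treatment assignment, no covariate effect on treatment."""
    return rt.SimulationConfig(
        n_subjects=n_subjects,
        covariates=[rt.CovariateSpec("x", "bernoulli", (0.5,))],
        risk_coefficients=[-1.0, 0.8],
        treatment_effect_B_vs_A=-0.5,
        confounding_coefficients=[0.0, 0.0],
        grace_period_days=14,
        horizon_days=1826,
        seed=seed,
    )


def toy_cohort(
    x, treatment, outcome, event_offset=None, start_offset=None
) -> pd.DataFrame:
    """Hand-built cohort frame for enumerable examples."""
    n = len(outcome)
    return pd.DataFrame(
        {
            "id": [f"T{i:03d}" for i in range(n)],
            "x": np.asarray(x, dtype=float),
            "treatment": list(treatment),
            "treatment_start_offset_days": (
                np.zeros(n, dtype=int) if start_offset is None else start_offset
            ),
            "outcome": np.asarray(outcome, dtype=int),
            "event_offset_days": pd.array(
                [
                    (event_offset[i] if event_offset is not None else 100)
                    if outcome[i] == 1
                    else None
                    for i in range(n)
                ],
                dtype="Int64",
            ),
        }
    )


@pytest.fixture(scope="session")
def confounded_cohort():
    cfg = confounded_config(5000, seed=42)
    return rt.simulate_cohort(cfg)


@pytest.fixture
def no_grace():
    return rt.EligibilitySpec(grace_period_days=0, horizon_days=1826)


@pytest.fixture
def grace14():
    return rt.EligibilitySpec(grace_period_days=14, horizon_days=1826)
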