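"""Nonparametric bootstrap inference for the intention-to-treat contrast.

Both arm means are computed from the same eligible subjects: everyone enters
the standard-of-care mean, and the same people — stratified by risk — enter
the rule-arm mean. A variance estimate must respect this shared-subject
dependence, so the resampling unit is the subject across the WHOLE eligible
cohort (never per-arm): each bootstrap draw re-runs the entire estimation
pipeline (grace-period handling, strata, Q-model fits, both arm means, the
contrast) on the resampled cohort, via the very same code path as the point
estimate.

Replicates in which a stratum loses positivity (or a Q model becomes
unfittable) are dropped and counted; losing more than 20% of replicates is
treated as a failure of the bootstrap rather than silently reported.
The interval is the percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import emulate
from .errors import ConfigurationError, FittingError, InferenceError, PositivityError
from .rules import DecisionRule

_MAX_FAILED_FRACTION = 0.2


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary for delta.

    ``ci_lower <= ci_upper`` always holds; the point estimate is not forced
    inside the interval (percentile intervals may exclude it in skewed
    finite samples). ``n_failed`` counts replicates dropped for positivity
    or fitting failures; ``replicates`` holds the surviving delta* values.
    """

    point_estimate: float
    replicates: np.ndarray
    ci_lower: float
    ci_upper: float
    level: float
    n_boot: int
    n_failed: int
    seed: int

    @property
    def se(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0

    def dump_replicates(self, path: str | Path) -> None:
        pd.DataFrame({"delta": self.replicates}).to_csv(path, index=False)


def bootstrap_delta(
    cohort: pd.DataFrame,
    risks: Sequence[float],
    rule: DecisionRule,
    q_spec: emulate.QModelSpec,
    spec: emulate.EligibilitySpec,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
    action_space: Sequence[str] = ("A", "B"),
) -> BootstrapResult:
    """Bootstrap the emulated-trial contrast delta on an eligible cohort.

    Resamples subjects with replacement from the full eligible cohort and
    recomputes :func:`ruletrial.emulate.estimate_delta` per replicate;
    reproducible given ``seed``.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    if not 0.0 < level < 1.0:
        raise ConfigurationError("confidence level must be in (0, 1)")
    risks = np.asarray(risks, dtype=float)

    point = emulate.estimate_delta(
        cohort, risks, rule, q_spec, spec,
        action_space=action_space, compute_positivity=False,
    ).delta

    n = len(cohort)
    rng = np.random.default_rng(seed)
    replicates: list[float] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot_cohort = cohort.iloc[idx].reset_index(drop=True)
        try:
            result = emulate.estimate_delta(
                boot_cohort, risks[idx], rule, q_spec, spec,
                action_space=action_space, compute_positivity=False,
            )
        except (PositivityError, FittingError):
            n_failed += 1
            continue
        replicates.append(result.delta)

    if n_failed / n_boot > _MAX_FAILED_FRACTION:
        raise InferenceError(
            f"{n_failed}/{n_boot} bootstrap replicates lost positivity or failed "
            "to fit; increase the sample size or coarsen the Q model"
        )
    reps = np.asarray(replicates)
    alpha = 1.0 - level
    ci_lower, ci_upper = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(
        point_estimate=point,
        replicates=reps,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        level=level,
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )
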