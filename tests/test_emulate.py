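"""Emulated-trial machinery: eligibility, grace period, Q models,
g-computation, the two arm means, and the contrast."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ruletrial as rt
from ruletrial.errors import (
    DataError,
    EstimationError,
    FittingError,
    PositivityError,
    SchemaError,
)
from ruletrial.synthetic_cohort import OUTCOME, TREATMENT

from conftest import confounded_config, randomized_config, toy_cohort


class TestEligibility:
    def test_all_pass_is_identity(self):
        cohort = toy_cohort(x=[1, 2, 3], treatment="AAB", outcome=[0, 1, 0])
        spec = rt.EligibilitySpec(criteria=[("anyone", "x == x")])
        kept = rt.apply_eligibility(cohort, spec)
        assert len(kept) == 3

    def test_age_filter_by_hand(self):
        cohort = toy_cohort(x=[17, 18, 40], treatment="AAB", outcome=[0, 1, 0])
        spec = rt.EligibilitySpec(criteria=[("adults", "x >= 18")])
        kept = rt.apply_eligibility(cohort, spec)
        assert len(kept) == 2
        assert kept.attrs["eligibility_exclusions"] == {"adults": 1}

    def test_contradictory_criteria_give_empty_table_not_exception(self):
        cohort = toy_cohort(x=[1, 2], treatment="AB", outcome=[0, 1])
        spec = rt.EligibilitySpec(criteria=[("lo", "x < 1"), ("hi", "x > 2")])
        kept = rt.apply_eligibility(cohort, spec)
        assert len(kept) == 0

    def test_callable_predicate(self):
        cohort = toy_cohort(x=[1, 2, 3], treatment="AAB", outcome=[0, 1, 0])
        spec = rt.EligibilitySpec(criteria=[("odd", lambda df: df["x"] % 2 == 1)])
        assert len(rt.apply_eligibility(cohort, spec)) == 2

    def test_missing_column_is_schema_error(self):
        cohort = toy_cohort(x=[1], treatment="A", outcome=[0])
        spec = rt.EligibilitySpec(criteria=[("bad", "age >= 18")])
        with pytest.raises(SchemaError, match="bad"):
            rt.apply_eligibility(cohort, spec)


class TestGracePeriodPartition:
    def test_boundary_inclusive_partition(self):
        cohort = toy_cohort(
            x=[0, 0, 0], treatment="AAB", outcome=[1, 1, 1],
            event_offset=[3, 14, 15],
        )
        spec = rt.EligibilitySpec(grace_period_days=14)
        early, main = rt.grace_period_partition(cohort, spec)
        assert list(early["event_offset_days"]) == [3, 14]
        assert list(main["event_offset_days"]) == [15]

    def test_zero_grace_only_offset_zero_is_early(self):
        cohort = toy_cohort(
            x=[0, 0], treatment="AA", outcome=[1, 1], event_offset=[0, 1]
        )
        spec = rt.EligibilitySpec(grace_period_days=0)
        early, main = rt.grace_period_partition(cohort, spec)
        assert list(early["event_offset_days"]) == [0]
        assert len(main) == 1

    def test_no_events_no_early_set(self):
        cohort = toy_cohort(x=[0, 1], treatment="AB", outcome=[0, 0])
        early, main = rt.grace_period_partition(
            cohort, rt.EligibilitySpec(grace_period_days=14)
        )
        assert len(early) == 0 and len(main) == 2

    def test_negative_offsets_are_a_data_error(self):
        cohort = toy_cohort(x=[0], treatment="A", outcome=[1], event_offset=[-1])
        with pytest.raises(DataError):
            rt.grace_period_partition(cohort, rt.EligibilitySpec(grace_period_days=14))


class TestFitQModel:
    def test_treatment_only_model_reproduces_subgroup_means(self):
        cohort = toy_cohort(
            x=[0] * 8, treatment="AAAABBBB", outcome=[0, 0, 1, 1, 0, 1, 1, 1]
        )
        q = rt.fit_q_model(cohort, rt.QModelSpec())
        assert q.predict(cohort, "A").mean() == pytest.approx(0.5, abs=1e-9)
        assert q.predict(cohort, "B").mean() == pytest.approx(0.75, abs=1e-9)

    def test_single_treatment_subgroup_is_positivity_error(self):
        cohort = toy_cohort(x=[0, 1, 0], treatment="AAA", outcome=[0, 1, 0])
        with pytest.raises(PositivityError, match="low"):
            rt.fit_q_model(cohort, rt.QModelSpec(), stratum="low")

    def test_constant_outcome_is_fitting_error(self):
        cohort = toy_cohort(x=[0, 1, 0, 1], treatment="ABAB", outcome=[0, 0, 0, 0])
        with pytest.raises(FittingError):
            rt.fit_q_model(cohort, rt.QModelSpec())

    def test_recovers_generating_treatment_effect(self):
        # randomized assignment, null covariate effect: the fitted treatment
        # coefficient estimates the generating log-odds shift; statsmodels'
        # own standard error is the Monte-Carlo yardstick
        cfg = randomized_config(20_000, seed=31)
        cfg.risk_coefficients = [-1.0, 0.0]
        cohort, _ = rt.simulate_cohort(cfg)
        q = rt.fit_q_model(cohort, rt.QModelSpec())
        X = np.column_stack(
            [np.ones(len(cohort)), (cohort[TREATMENT] == "B").astype(float)]
        )
        se = sm.Logit(cohort[OUTCOME].to_numpy(), X).fit(disp=0).bse[1]
        effect = q.coefficients[1]
        assert abs(effect - (-0.5)) < 3 * se


class TestGcompMean:
    def test_matches_nonparametric_standardization(self):
        # saturated Q model vs the brute-force standardization formula
        cohort, _ = rt.simulate_cohort(confounded_config(400, seed=51))
        q_spec = rt.QModelSpec(covariate_names=["x"],
                               treatment_covariate_interactions=["x"])
        qmodel = rt.fit_q_model(cohort, q_spec)
        for t in ("A", "B"):
            oracle = sum(
                (cohort["x"] == x).mean()
                * cohort.loc[
                    (cohort["x"] == x) & (cohort[TREATMENT] == t), OUTCOME
                ].mean()
                for x in (0.0, 1.0)
            )
            assert rt.gcomp_mean(qmodel, cohort, t) == pytest.approx(oracle, abs=1e-10)

    def test_randomized_treatment_only_reduces_to_stratified_mean(self):
        cohort, _ = rt.simulate_cohort(randomized_config(2000, seed=52))
        qmodel = rt.fit_q_model(cohort, rt.QModelSpec())
        for t in ("A", "B"):
            observed = cohort.loc[cohort[TREATMENT] == t, OUTCOME].mean()
            assert rt.gcomp_mean(qmodel, cohort, t) == pytest.approx(observed, abs=1e-9)

    def test_twelve_row_toy_by_hand(self):
        # three subjects per (treatment, x) cell; cell means:
        # (A,0)=1/3, (A,1)=2/3, (B,0)=2/3, (B,1)=1/3; P(x=0)=P(x=1)=1/2
        cohort = toy_cohort(
            x=[0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1],
            treatment="AAAAAABBBBBB",
            outcome=[1, 0, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0],
        )
        q_spec = rt.QModelSpec(covariate_names=["x"],
                               treatment_covariate_interactions=["x"])
        qmodel = rt.fit_q_model(cohort, q_spec)
        assert rt.gcomp_mean(qmodel, cohort, "A") == pytest.approx(0.5, abs=1e-9)
        assert rt.gcomp_mean(qmodel, cohort, "B") == pytest.approx(0.5, abs=1e-9)

    def test_unseen_treatment_rejected(self):
        cohort = toy_cohort(x=[0, 1, 0, 1], treatment="ABAB", outcome=[0, 1, 1, 0])
        qmodel = rt.fit_q_model(cohort, rt.QModelSpec())
        with pytest.raises(rt.errors.ConfigurationError):
            rt.gcomp_mean(qmodel, cohort, "C")


class TestRuleArmMean:
    def test_factual_rule_with_saturated_q_reproduces_event_proportion(
        self, confounded_cohort, grace14
    ):
        cohort, pot = confounded_cohort
        risks = pot["true_risk"].to_numpy()
        q_spec = rt.QModelSpec(covariate_names=["x"],
                               treatment_covariate_interactions=["x"])
        mean, _ = rt.estimate_rule_mean(
            cohort, risks, rt.FactualTreatmentRule(cutoff=0.35), q_spec, grace14
        )
        assert mean == pytest.approx(cohort[OUTCOME].mean(), abs=1e-8)

    def test_entirely_early_cohort_returns_one(self, grace14):
        cohort = toy_cohort(
            x=[0, 1, 0], treatment="AAB", outcome=[1, 1, 1], event_offset=[1, 5, 14]
        )
        mean, decomp = rt.estimate_rule_mean(
            cohort, np.array([0.2, 0.6, 0.4]), rt.DecisionRule(0.5, "A", "B"),
            rt.QModelSpec(), grace14,
        )
        assert mean == 1.0
        assert decomp.n_early == 3

    def test_decomposition_identity(self, confounded_cohort, grace14):
        cohort, pot = confounded_cohort
        risks = pot["true_risk"].to_numpy()
        mean, decomp = rt.estimate_rule_mean(
            cohort, risks, rt.DecisionRule(0.35, "A", "B"),
            rt.QModelSpec(covariate_names=["x"]), grace14,
        )
        weighted = sum(c.weight * c.mean for c in decomp.components if c.n > 0)
        assert mean == pytest.approx(weighted, abs=1e-12)
        assert sum(c.n for c in decomp.components) == decomp.n_eligible

    def test_misaligned_risks_rejected(self, grace14):
        cohort = toy_cohort(x=[0, 1], treatment="AB", outcome=[0, 1])
        with pytest.raises(rt.errors.AlignmentError):
            rt.estimate_rule_mean(cohort, np.array([0.5]),
                                  rt.DecisionRule(0.5, "A", "B"),
                                  rt.QModelSpec(), grace14)

    def test_unobserved_assigned_treatment_is_positivity_error(self, grace14):
        cohort = toy_cohort(x=[0, 1, 0, 1], treatment="AAAA", outcome=[0, 1, 0, 1])
        with pytest.raises(PositivityError):
            rt.estimate_rule_mean(cohort, np.full(4, 0.9),
                                  rt.DecisionRule(0.5, "A", "B"),
                                  rt.QModelSpec(), grace14)


class TestSocMean:
    def test_sample_proportion(self, no_grace):
        cohort = toy_cohort(x=[0] * 4, treatment="AABB", outcome=[1, 0, 0, 1])
        assert rt.estimate_soc_mean(cohort, no_grace) == 0.5

    def test_all_zero_outcomes(self, no_grace):
        cohort = toy_cohort(x=[0] * 3, treatment="AAB", outcome=[0, 0, 0])
        assert rt.estimate_soc_mean(cohort, no_grace) == 0.0

    def test_equals_one_line_oracle(self, confounded_cohort, no_grace):
        cohort, _ = confounded_cohort
        assert rt.estimate_soc_mean(cohort, no_grace) == float(
            np.mean(cohort[OUTCOME])
        )

    def test_empty_cohort_is_estimation_error(self, no_grace):
        cohort = toy_cohort(x=[], treatment="", outcome=[])
        with pytest.raises(EstimationError):
            rt.estimate_soc_mean(cohort, no_grace)


class TestEstimateDelta:
    def test_factual_rule_gives_zero_delta(self, confounded_cohort, grace14):
        cohort, pot = confounded_cohort
        risks = pot["true_risk"].to_numpy()
        q_spec = rt.QModelSpec(covariate_names=["x"],
                               treatment_covariate_interactions=["x"])
        result = rt.estimate_delta(
            cohort, risks, rt.FactualTreatmentRule(cutoff=0.35), q_spec, grace14
        )
        assert result.delta == pytest.approx(0.0, abs=1e-8)

    def test_result_invariants(self, confounded_cohort, grace14):
        cohort, pot = confounded_cohort
        risks = pot["true_risk"].to_numpy()
        result = rt.estimate_delta(
            cohort, risks, rt.DecisionRule(0.35, "A", "B"),
            rt.QModelSpec(covariate_names=["x"]), grace14,
        )
        assert result.stratum_weights["low"] + result.stratum_weights["high"] == (
            pytest.approx(1.0, abs=1e-12)
        )
        assert result.n_low + result.n_high == result.n_eligible
        assert result.delta == result.mean_pred_arm - result.mean_soc_arm
        assert 0.0 <= result.mean_pred_arm <= 1.0
        assert 0.0 <= result.mean_soc_arm <= 1.0


class TestCheckPositivity:
    def test_unobserved_treatment_is_hard_flagged(self):
        cohort = toy_cohort(x=[0, 1, 0, 1], treatment="AAAA", outcome=[0, 1, 0, 1])
        report = rt.check_positivity(
            cohort, np.full(4, 0.9), rt.DecisionRule(0.5, "A", "B"),
            rt.QModelSpec(covariate_names=["x"]),
        )
        assert report.hard_flags and not report.ok

    def test_balanced_randomized_cohort_has_no_flags(self):
        cohort, pot = rt.simulate_cohort(randomized_config(5000, seed=61))
        report = rt.check_positivity(
            cohort, pot["true_risk"].to_numpy(), rt.DecisionRule(0.3, "A", "B"),
            rt.QModelSpec(covariate_names=["x"]), floor=5,
        )
        assert report.ok and not report.flags

    def test_empty_stratum_reported_not_flagged(self):
        cohort = toy_cohort(x=[0, 1], treatment="AB", outcome=[0, 1])
        report = rt.check_positivity(
            cohort, np.array([0.6, 0.9]), rt.DecisionRule(0.0, "A", "B"),
            rt.QModelSpec(),
        )
        assert report.stratum_sizes["low"] == 0
        assert not any("'low'" in f for f in report.hard_flags)

    def test_continuous_covariates_are_decile_binned(self):
        cohort, pot = rt.simulate_cohort(
            rt.SimulationConfig(
                n_subjects=2000,
                covariates=[rt.CovariateSpec("age", "normal", (40.0, 10.0))],
                risk_coefficients=[-1.0, 0.0],
                treatment_effect_B_vs_A=0.0,
                confounding_coefficients=[0.0, 0.0],
                seed=62,
            )
        )
        report = rt.check_positivity(
            cohort, pot["true_risk"].to_numpy(), rt.DecisionRule(0.0, "A", "B"),
            rt.QModelSpec(covariate_names=["age"]),
        )
        assert len([c for c in report.cells if c.covariate == "age"]) == 10
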