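"""MNL estimation, interactions, anchoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from dceana.core import ATTRIBUTE_COLUMNS, ChoiceSet, Profile
from dceana.data import ChoiceDataset
from dceana.mnl import (
    AnchoringError,
    anchor,
    choice_probability,
    fit_mnl,
    fit_mnl_interactions,
    full_attender_decrements,
)


def _dataset_from_choices(rows):
    return ChoiceDataset(
        pd.DataFrame(
            rows,
            columns=["respondent_id", "task_id", "option", *ATTRIBUTE_COLUMNS, "chosen"],
        )
    )


class TestChoiceProbability:
    def test_zero_beta_is_even_odds(self):
        cs = ChoiceSet(Profile.from_label("12345"), Profile.from_label("54321"))
        assert choice_probability(np.zeros(20), cs) == (0.5, 0.5)

    def test_better_state_preferred_under_negative_coefficients(self):
        cs = ChoiceSet(Profile.from_label("11111"), Profile.from_label("55555"))
        p_a, p_b = choice_probability(np.full(20, -0.5), cs)
        assert p_a > 0.5
        assert p_a + p_b == pytest.approx(1.0)

    def test_single_attribute_closed_form(self):
        # options differ only in MO level 2 with coefficient -1:
        # P(better) = 1 / (1 + e^-1)
        beta = np.zeros(20)
        beta[0] = -1.0
        cs = ChoiceSet(Profile.from_label("11111"), Profile.from_label("21111"))
        p_a, _ = choice_probability(beta, cs)
        assert p_a == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))

    def test_location_invariance_via_shared_levels(self):
        # raising both options by the same attribute level shifts both
        # utilities equally and leaves the probabilities unchanged
        beta = np.linspace(-1, -0.1, 20)
        p1 = choice_probability(beta, ChoiceSet(Profile.from_label("21111"), Profile.from_label("31111")))
        p2 = choice_probability(beta, ChoiceSet(Profile.from_label("21115"), Profile.from_label("31115")))
        assert p1 == pytest.approx(p2)


class TestFitMNL:
    def test_parameter_recovery_coverage(self, full_attendance_cohort):
        """Estimates land inside their own 95% CIs for >= 17/20 parameters."""
        fit = full_attendance_cohort["fit"]
        true = full_attendance_cohort["scenario"].true_beta
        assert fit.converged
        inside = np.abs(fit.beta - true) <= 1.96 * fit.se
        assert inside.sum() >= 17

    def test_agrees_with_direct_likelihood_optimization(self, recovery_runs):
        """Independent route: scipy BFGS on the hand-written log-likelihood."""
        data = recovery_runs[0]["data"]
        fit = fit_mnl(data)
        _, Z, y = data.design_arrays()

        def nll(b):
            s = 2 * y - 1
            return np.logaddexp(0.0, -s * (Z @ b)).sum()

        res = minimize(nll, np.zeros(20), method="BFGS", options={"gtol": 1e-8})
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_fitted_loglik_dominates_null(self, recovery_runs):
        data = recovery_runs[0]["data"]
        fit = fit_mnl(data)
        assert fit.loglik >= -data.n_tasks * math.log(2)

    def test_fit_statistics_identities(self, recovery_runs):
        fit = fit_mnl(recovery_runs[0]["data"])
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 20)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 20 * math.log(fit.n_obs))

    def test_separation_flagged_not_raised(self):
        rows = []
        for r in range(4):
            for t in range(1, 6):
                rows.append((r, t, "A", 1, 1, 1, 1, 1, 1))
                rows.append((r, t, "B", 5, 5, 5, 5, 5, 0))
        with pytest.warns(UserWarning):
            fit = fit_mnl(_dataset_from_choices(rows))
        assert not fit.converged
        assert fit.message != ""


class TestInteractions:
    def test_null_interactions_rarely_significant(self):
        """Two groups simulated with identical preferences: interaction
        terms should be significant at most ~5% of the time."""
        from dceana.eclc import AttendancePattern, ECLCSpec
        from dceana.simulate import default_scenario, simulate

        sc = default_scenario(0, seed=8)
        sc.spec = ECLCSpec((AttendancePattern.full(),))
        sc.class_probs = np.array([1.0])
        sc.n_respondents = 1000
        data, _ = simulate(sc)
        flags = {r: int(i % 2 == 0) for i, r in enumerate(data.respondents)}
        fit = fit_mnl_interactions(data, flags)
        assert len(fit.beta) == 40
        assert (fit.pvalues[20:] < 0.05).sum() <= 2  # 10% of 20

    def test_single_group_reduces_to_main_effects(self, recovery_runs):
        data = recovery_runs[0]["data"]
        flags = {r: 1 for r in data.respondents}
        with pytest.warns(UserWarning):
            fit = fit_mnl_interactions(data, flags)
        np.testing.assert_allclose(fit.beta[:20], fit_mnl(data).beta, atol=1e-10)

    def test_full_attender_decrement_is_main_plus_interaction(self):
        beta = np.concatenate([np.full(20, -0.4), np.full(20, -0.7)])
        from dceana.mnl import InteractionFit

        fit = InteractionFit(
            beta=beta, se=np.ones(40), vcov=np.eye(40), loglik=0.0,
            aic=0.0, bic=0.0, n_obs=1, converged=True,
            param_names=tuple(f"p{i}" for i in range(40)),
        )
        np.testing.assert_allclose(full_attender_decrements(fit), np.full(20, -1.1))


class TestAnchor:
    def test_equal_level5_split(self):
        beta = np.full(20, -0.5)
        beta[[3, 7, 11, 15, 19]] = -1.0
        anchored = anchor(beta)
        np.testing.assert_allclose(anchored[[3, 7, 11, 15, 19]], 0.2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        beta = -np.abs(rng.normal(0.5, 0.2, 20))
        np.testing.assert_allclose(anchor(2 * beta), anchor(beta))

    def test_worst_state_normalizes_to_one(self, recovery_runs):
        anchored = anchor(recovery_runs[0]["fit"].beta)
        assert anchored[[3, 7, 11, 15, 19]].sum() == pytest.approx(1.0)

    def test_zero_decrement_rejected(self):
        beta = np.zeros(20)
        with pytest.raises(AnchoringError):
            anchor(beta)
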