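"""ECLC model: masking, likelihood, EM, five-step selection, classification."""

import math

import numpy as np
import pandas as pd
import pytest

from dceana.core import ATTRIBUTE_COLUMNS
from dceana.data import ChoiceDataset
from dceana.eclc import (
    AttendancePattern,
    ECLCSpec,
    StepwiseError,
    all_patterns,
    class_prob_cis,
    classify_respondents,
    eclc_loglik,
    fit_eclc,
    mask_beta,
    patterns_ignoring,
    stepwise_selection,
)
from dceana.mnl import fit_mnl
from dceana.simulate import default_scenario, simulate


class TestAttendancePatterns:
    def test_there_are_exactly_32(self):
        pats = all_patterns()
        assert len(pats) == 32
        assert len({p.attended for p in pats}) == 32
        assert pats[0].is_full

    def test_table_style_labels(self):
        assert AttendancePattern.full().label == "None"
        assert AttendancePattern.ignoring("PD", "AD").label == "PD+AD"
        assert AttendancePattern.all_ignored().label == "MO+SC+UA+PD+AD"
        assert AttendancePattern.from_label("PD+AD") == AttendancePattern.ignoring("PD", "AD")

    def test_duplicate_patterns_rejected_in_spec(self):
        with pytest.raises(ValueError):
            ECLCSpec((AttendancePattern.full(), AttendancePattern.ignoring()))


class TestMaskBeta:
    def test_full_attendance_is_identity(self):
        beta = np.linspace(-1, -0.05, 20)
        np.testing.assert_array_equal(mask_beta(beta, AttendancePattern.full()), beta)

    def test_all_ignored_zeroes_everything(self):
        beta = np.linspace(-1, -0.05, 20)
        assert not mask_beta(beta, AttendancePattern.all_ignored()).any()

    def test_pd_ad_ignored_zeroes_their_blocks(self):
        beta = -np.arange(1, 21, dtype=float)
        masked = mask_beta(beta, AttendancePattern.ignoring("PD", "AD"))
        assert not masked[12:20].any()
        np.testing.assert_array_equal(masked[:12], beta[:12])


def _tiny_dataset():
    """2 respondents x 2 tasks over fixed pairs."""
    rows = []
    tasks = [("21111", "11121"), ("33111", "11133")]
    choices = {0: [1, 0], 1: [0, 0]}  # respondent -> chose-A flags per task
    for r in (0, 1):
        for t, (a, b) in enumerate(tasks, start=1):
            ca = choices[r][t - 1]
            rows.append((r, t, "A", *[int(c) for c in a], ca))
            rows.append((r, t, "B", *[int(c) for c in b], 1 - ca))
    return ChoiceDataset(
        pd.DataFrame(
            rows,
            columns=["respondent_id", "task_id", "option", *ATTRIBUTE_COLUMNS, "chosen"],
        )
    )


class TestECLCLoglik:
    def test_single_full_class_equals_mnl_loglik(self, recovery_runs):
        data = recovery_runs[0]["data"]
        fit = fit_mnl(data)
        spec = ECLCSpec((AttendancePattern.full(),))
        assert eclc_loglik(fit.beta, np.array([1.0]), data, spec) == pytest.approx(
            fit.loglik, abs=1e-8
        )

    def test_all_ignored_class_is_coin_flip(self, recovery_runs):
        data = recovery_runs[0]["data"]
        spec = ECLCSpec((AttendancePattern.all_ignored(),))
        beta = np.linspace(-2, -0.1, 20)
        assert eclc_loglik(beta, np.array([1.0]), data, spec) == pytest.approx(
            -data.n_tasks * math.log(2)
        )

    def test_two_class_mixture_matches_hand_computation(self):
        """Brute-force arithmetic oracle on a 2-respondent, 2-task dataset."""
        data = _tiny_dataset()
        beta = np.zeros(20)
        beta[[0, 8]] = [-0.9, -0.4]  # MO2 and UA2
        spec = ECLCSpec((AttendancePattern.full(), AttendancePattern.ignoring("MO")))
        pi = np.array([0.7, 0.3])

        def p_choose_a(b, a_label, b_label, attended_mo):
            from dceana.core import Profile, encode_profile

            bb = b.copy()
            if not attended_mo:
                bb[0:4] = 0.0
            z = encode_profile(Profile.from_label(a_label)) - encode_profile(
                Profile.from_label(b_label)
            )
            return 1.0 / (1.0 + math.exp(-(z @ bb)))

        tasks = [("21111", "11121"), ("33111", "11133")]
        choices = {0: [1, 0], 1: [0, 0]}
        expected = 0.0
        for r in (0, 1):
            per_class = []
            for attended_mo in (True, False):
                lik = 1.0
                for t, (a, b) in enumerate(tasks):
                    pa = p_choose_a(beta, a, b, attended_mo)
                    lik *= pa if choices[r][t] else (1 - pa)
                per_class.append(lik)
            expected += math.log(pi[0] * per_class[0] + pi[1] * per_class[1])
        assert eclc_loglik(beta, pi, data, spec) == pytest.approx(expected, abs=1e-12)


class TestFitECLC:
    def test_recovers_class_probs_and_beta(self, recovery_runs):
        """Averaged over the seed prefix: class probabilities within 0.05
        and coefficient RMSE below 0.15."""
        truth_pi = recovery_runs[0]["scenario"].class_probs
        pis = np.mean([r["fit"].class_probs for r in recovery_runs], axis=0)
        np.testing.assert_allclose(pis, truth_pi, atol=0.05)
        rmses = [
            float(np.sqrt(np.mean((r["fit"].beta - r["scenario"].true_beta) ** 2)))
            for r in recovery_runs
        ]
        assert np.mean(rmses) < 0.15

    def test_full_only_spec_matches_mnl(self, recovery_runs):
        data = recovery_runs[0]["data"]
        mnl = fit_mnl(data)
        fit = fit_eclc(
            data, ECLCSpec((AttendancePattern.full(),)), seed=0, n_restarts=1
        )
        np.testing.assert_allclose(fit.beta, mnl.beta, atol=1e-5)
        assert fit.class_probs[0] == pytest.approx(1.0)

    def test_em_trace_monotone(self, recovery_runs):
        for r in recovery_runs:
            trace = r["fit"].em_trace
            assert all(b - a > -1e-8 for a, b in zip(trace, trace[1:]))

    def test_posteriors_are_distributions(self, recovery_runs):
        W = recovery_runs[0]["fit"].posteriors.to_numpy()
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)
        assert (W >= 0).all()


class TestStepwiseSelection:
    def test_step_class_counts(self, stepwise_run):
        """Six classes at step one; ten two-ignored additions at step two;
        ten three-ignored at step three; six at step four."""
        trace = stepwise_run["trace"]
        assert len(trace) == 5
        assert len(trace[0].labels) == 6
        kept = [len(t.labels) - len(t.dropped) for t in trace]
        assert len(trace[1].labels) == kept[0] + 10
        assert len(trace[2].labels) == kept[1] + 10
        assert len(trace[3].labels) == kept[2] + 6
        assert len(patterns_ignoring(2)) == 10
        assert len(patterns_ignoring(3)) == 10
        assert len(patterns_ignoring(4)) == 5

    def test_recovers_true_classes_exactly(self, stepwise_run):
        fit = stepwise_run["fit"]
        truth = set(stepwise_run["scenario"].spec.labels)
        assert set(fit.spec.labels) == truth
        assert (fit.class_probs >= 0.05).all()

    def test_dropped_classes_never_return(self, stepwise_run):
        dropped = set()
        for rec in stepwise_run["trace"]:
            assert not (dropped & set(rec.labels))
            dropped |= set(rec.dropped)

    def test_zero_threshold_keeps_all_32(self):
        sc = default_scenario(0, seed=5)
        sc.n_respondents = 60
        data, _ = simulate(sc)
        fit, trace = stepwise_selection(
            data, threshold=0.0, seed=0, screen_max_iter=30, max_iter=30
        )
        assert fit.spec.n_classes == 32
        assert [len(t.labels) for t in trace] == [6, 16, 26, 32, 32]


class TestClassification:
    def test_modal_posterior_rule(self, stepwise_run):
        fit = stepwise_run["fit"]
        cls = classify_respondents(fit)
        W = fit.posteriors
        full_col = fit.spec.labels.index("None")
        confident = W.iloc[:, full_col] > 0.9
        assert (cls[confident.to_numpy()] == "full").all()

    def test_accuracy_close_to_bayes_oracle(self, recovery_runs):
        """The estimated modal-posterior classifier cannot beat the Bayes
        classifier built from the true parameters; it should come close."""
        from dceana.eclc import _class_task_loglik, _respondent_loglik

        for r in recovery_runs:
            sc, data, labels = r["scenario"], r["data"], r["labels"]
            codes, Z, y = data.design_arrays()
            masks = sc.spec.mask_matrix()
            L = _respondent_loglik(
                _class_task_loglik(sc.true_beta, Z, y, masks), codes, data.n_respondents
            )
            oracle = np.argmax(np.log(sc.class_probs)[None, :] + L, axis=1)
            truth = (
                labels.set_index("respondent_id")["true_class"]
                .reindex(data.respondents)
                .to_numpy()
            )
            oracle_acc = float((oracle == truth).mean())
            est = classify_respondents(r["fit"])
            group_truth = labels.set_index("respondent_id")["attendance_group"]
            est_acc = float((est == group_truth.reindex(est.index)).mean())
            assert est_acc > 0.7
            assert est_acc >= oracle_acc - 0.03

    def test_tie_breaks_toward_larger_class(self):
        spec = ECLCSpec((AttendancePattern.full(), AttendancePattern.ignoring("AD")))
        from dceana.eclc import ECLCFit

        fit = ECLCFit(
            beta=np.zeros(20),
            class_probs=np.array([0.6, 0.4]),
            spec=spec,
            posteriors=pd.DataFrame([[0.5, 0.5]], index=[0], columns=spec.labels),
            loglik=0.0, aic=0.0, bic=0.0, em_trace=[0.0],
            n_params=21, converged=True,
        )
        assert classify_respondents(fit).iloc[0] == "full"


class TestClassProbCIs:
    def test_cis_contain_point_estimates_and_shrink(self):
        sc_small = default_scenario(0, seed=6)
        sc_small.n_respondents = 150
        data_s, _ = simulate(sc_small)
        fit_s = fit_eclc(data_s, sc_small.spec, seed=0, n_restarts=1)
        ci_s = class_prob_cis(fit_s, data_s, n_boot=20, seed=3)
        assert (ci_s["ci_lo"].to_numpy() <= fit_s.class_probs + 1e-12).all()
        assert (ci_s["ci_hi"].to_numpy() >= fit_s.class_probs - 1e-12).all()

        sc_big = default_scenario(0, seed=6)
        sc_big.n_respondents = 600
        data_b, _ = simulate(sc_big)
        fit_b = fit_eclc(data_b, sc_big.spec, seed=0, n_restarts=1)
        ci_b = class_prob_cis(fit_b, data_b, n_boot=20, seed=3)
        width_s = (ci_s["ci_hi"] - ci_s["ci_lo"]).mean()
        width_b = (ci_b["ci_hi"] - ci_b["ci_lo"]).mean()
        assert width_b < width_s

    def test_degenerate_single_class_ci(self, recovery_runs):
        data = recovery_runs[0]["data"]
        small = data.subset(data.respondents[:40])
        fit = fit_eclc(
            small, ECLCSpec((AttendancePattern.full(),)), seed=0, n_restarts=1
        )
        ci = class_prob_cis(fit, small, n_boot=5, seed=0)
        assert ci["ci_lo"].iloc[0] == pytest.approx(1.0)
        assert ci["ci_hi"].iloc[0] == pytest.approx(1.0)

    def test_too_few_bootstraps_rejected(self, recovery_runs):
        with pytest.raises(ValueError):
            class_prob_cis(recovery_runs[0]["fit"], recovery_runs[0]["data"], n_boot=1)
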