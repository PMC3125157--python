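"""Prediction errors, regret, design-matrix assembly and beta recovery."""

import numpy as np
import pandas as pd
import pytest

import cfbandit as cb
from cfbandit.design import (DesignMatrix, build_design_matrix,
                             build_regressor_set, convolve_events,
                             prediction_errors, regret_signal,
                             synthetic_bold_recovery)
from cfbandit.learner import ProbabilityEstimates, run_learner


@pytest.fixture(scope="module")
def regressors(agent_session, estimates):
    return build_regressor_set(agent_session, estimates)


@pytest.fixture(scope="module")
def dmatrix(agent_session, regressors):
    return build_design_matrix(agent_session, regressors)


def trial_row(condition=2, fc=1, sc=2, mags=(30, 80, 20), outcomes=(0, 1, 0)):
    return pd.Series({
        "condition": condition, "first_choice": fc, "second_choice": sc,
        "mag_1": mags[0], "mag_2": mags[1], "mag_3": mags[2],
        "outcome_1": outcomes[0], "outcome_2": outcomes[1],
        "outcome_3": outcomes[2],
    })


class TestPredictionErrors:
    def test_signed_arithmetic_and_bounds(self, agent_session, estimates,
                                          regressors):
        pe_cols = ["chosen_pe", "cf_pe_best_unchosen", "cf_pe_worst_unchosen",
                   "second_chosen_pe", "second_unchosen_pe"]
        vals = regressors[pe_cols].to_numpy()
        vals = vals[~np.isnan(vals)]
        assert np.all(vals >= -1) and np.all(vals <= 1)
        # spot check: chosen PE is outcome minus the pre-outcome estimate
        i = 10
        fc = int(agent_session["first_choice"].iloc[i])
        expect = (agent_session[f"outcome_{fc}"].iloc[i]
                  - estimates.p_hat[i, fc - 1])
        assert regressors["chosen_pe"].iloc[i] == pytest.approx(expect)

    def test_perfect_prediction_gives_zero_error(self):
        sess = pd.DataFrame({
            "condition": [1], "first_choice": [1], "second_choice": [np.nan],
            "mag_1": [50], "mag_2": [50], "mag_3": [50],
            "outcome_1": [1], "outcome_2": [0], "outcome_3": [0],
        })
        p = np.array([[1 - 1e-12, 1e-12, 0.25]])
        pe = prediction_errors(sess, ProbabilityEstimates(p))
        assert pe["chosen_pe"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_quarter_expectation_rewarded(self):
        sess = pd.DataFrame({
            "condition": [1], "first_choice": [1], "second_choice": [np.nan],
            "mag_1": [50], "mag_2": [50], "mag_3": [50],
            "outcome_1": [1], "outcome_2": [1], "outcome_3": [0],
        })
        pe = prediction_errors(sess, ProbabilityEstimates(
            np.array([[0.25, 0.5, 0.5]])))
        assert pe["chosen_pe"].iloc[0] == pytest.approx(0.75)

    def test_missing_outcome_rejected(self, agent_session, estimates):
        broken = agent_session.copy()
        broken.loc[0, "outcome_1"] = np.nan
        with pytest.raises(ValueError):
            build_regressor_set(broken, estimates)

    def test_chosen_pe_calibrated_for_optimal_learner(self, agent_session,
                                                      regressors):
        # a calibrated learner's chosen prediction errors average near zero
        assert abs(regressors["chosen_pe"].mean()) < 0.1


class TestRegret:
    def test_both_unrewarded_is_zero(self):
        assert regret_signal(trial_row(outcomes=(0, 0, 0))) == 0.0

    def test_foregone_reward_is_positive(self):
        # second decision between options 2 (chosen) and 3: option 3 pays 80
        row = trial_row(fc=1, sc=2, mags=(30, 60, 80), outcomes=(0, 0, 1))
        assert regret_signal(row) == pytest.approx(80.0)

    def test_own_reward_is_negative(self):
        row = trial_row(fc=3, sc=1, mags=(100, 20, 50), outcomes=(1, 0, 1))
        assert regret_signal(row) == pytest.approx(-100.0)

    def test_condition3_uses_reset_magnitudes(self):
        row = trial_row(condition=3, fc=1, sc=2, mags=(30, 60, 80),
                        outcomes=(0, 0, 1))
        assert regret_signal(row) == pytest.approx(50.0)

    def test_condition1_has_no_regret_phase(self):
        with pytest.raises(ValueError):
            regret_signal(trial_row(condition=1, sc=np.nan))

    def test_regret_separable_from_counterfactual_pe(self, regressors):
        # the dissociation requires the two signals not to be collinear
        sub = regressors.dropna(subset=["regret", "second_unchosen_pe"])
        r = np.corrcoef(sub["regret"], sub["second_unchosen_pe"])[0, 1]
        assert abs(r) < 0.8


class TestDesignMatrix:
    def test_full_request_has_24_columns(self, dmatrix):
        assert dmatrix.frame.shape[1] == 24
        assert len(dmatrix.task_columns) == 18
        assert np.all(dmatrix.frame[dmatrix.placeholder_columns] == 0)

    def test_task_columns_full_rank_across_seeds(self, small_grid):
        for seed in range(20):
            sched = cb.generate_true_probability_walk(180, seed=seed)
            skel = cb.generate_session(sched, seed=seed)
            sess = cb.simulate_agent(skel, sched, cb.ChoiceParams(6, 3, 4),
                                     "optimal", seed=seed, grid=small_grid)
            est = run_learner(sess, "optimal", grid=small_grid)
            dm = build_design_matrix(sess, build_regressor_set(sess, est))
            assert dm.task_rank() == len(dm.task_columns)

    def test_all_zero_modulator_column_is_zero(self):
        col = convolve_events(np.array([10.0, 40.0, 70.0]), tr=3.0,
                              n_volumes=40,
                              modulator=np.array([0.0, 0.0, 0.0]))
        assert np.allclose(col, 0.0)

    def test_events_beyond_scan_rejected(self, agent_session, regressors):
        with pytest.raises(ValueError):
            build_design_matrix(agent_session, regressors, n_volumes=10)

    def test_pe_column_decomposes_into_outcome_minus_expectation(
            self, agent_session, regressors):
        # mean-centering and HRF convolution are linear, so the PE
        # regressor equals outcome minus expectation column-wise
        c23 = agent_session["condition"] != 1
        onsets = agent_session.loc[c23, "t_fb2"].to_numpy()
        pe = regressors.loc[c23, "second_unchosen_pe"].to_numpy()
        outcome = regressors.loc[c23, "second_unchosen_outcome"].to_numpy()
        # the second unchosen option is the choice-ranked worst option
        expectation = regressors.loc[c23, "worst_unchosen_p_choice"].to_numpy()
        kw = dict(tr=3.0, n_volumes=int(np.nanmax(onsets) / 3.0) + 10)
        col_pe = convolve_events(onsets, modulator=pe, **kw)
        col_out = convolve_events(onsets, modulator=outcome, **kw)
        col_exp = convolve_events(onsets, modulator=expectation, **kw)
        assert np.allclose(col_pe, col_out - col_exp, atol=1e-10)


class TestBoldRecovery:
    def test_noiseless_recovery_is_exact(self, dmatrix):
        truth = np.linspace(-2, 2, len(dmatrix.task_columns))
        est, err = synthetic_bold_recovery(dmatrix, truth, noise_sd=0.0,
                                           seed=0)
        assert err < 1e-8

    def test_error_shrinks_with_scan_length(self, agent_session, regressors):
        rng = np.random.default_rng(5)
        long_dm = build_design_matrix(agent_session, regressors)
        n_long = long_dm.frame.shape[0]
        truth = rng.normal(size=len(long_dm.task_columns))
        short = DesignMatrix(frame=long_dm.frame.iloc[:n_long // 3],
                             tr=long_dm.tr)
        errs = {}
        for name, dm in (("short", short), ("long", long_dm)):
            trials = [synthetic_bold_recovery(dm, truth, noise_sd=2.0,
                                              seed=s)[1]
                      for s in range(10)]
            errs[name] = np.mean(trials)
        assert errs["long"] < errs["short"]

    def test_column_permutation_permutes_betas(self, dmatrix):
        rng = np.random.default_rng(6)
        truth = rng.normal(size=len(dmatrix.task_columns))
        perm = rng.permutation(len(dmatrix.task_columns))
        permuted = DesignMatrix(
            frame=dmatrix.frame[[dmatrix.task_columns[i] for i in perm]
                                + dmatrix.placeholder_columns],
            tr=dmatrix.tr)
        a, _ = synthetic_bold_recovery(dmatrix, truth, noise_sd=0.0, seed=7)
        b, _ = synthetic_bold_recovery(permuted, truth[perm], noise_sd=0.0,
                                       seed=7)
        assert np.allclose(a.to_numpy()[perm], b.to_numpy(), atol=1e-8)

    def test_wrong_beta_count_rejected(self, dmatrix):
        with pytest.raises(ValueError):
            synthetic_bold_recovery(dmatrix, np.ones(3), noise_sd=0.0)
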