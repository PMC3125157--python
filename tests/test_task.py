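"""Task simulation: schedules, session structure, simulated agents."""

import numpy as np
import pandas as pd
import pytest

import cfbandit as cb
from cfbandit.choice import choice_probabilities, second_phase_options, subjective_values
from cfbandit.task import (SessionConfig, generate_session,
                           generate_true_probability_walk,
                           read_session_tsv, select_decorrelated_schedule,
                           simulate_agent, write_session_tsv)


class TestProbabilityWalk:
    def test_zero_volatility_is_degenerate(self):
        sched = generate_true_probability_walk(50, volatility=0.0, seed=3)
        assert np.allclose(sched.true_prob, sched.true_prob[0])

    def test_support_open_unit_interval(self):
        sched = generate_true_probability_walk(180, seed=11)
        assert sched.true_prob.shape == (180, 3)
        assert np.all(sched.true_prob > 0) and np.all(sched.true_prob < 1)

    def test_single_step_variance_matches_configuration(self):
        # many independent single steps from mean 0.5: empirical variance
        # of the step should match the configured beta variance
        v = 1e-3
        steps = np.array([
            generate_true_probability_walk(
                2, volatility=v, n_options=1, seed=s,
                initial_range=(0.5, 0.5)).true_prob[1, 0]
            for s in range(10_000)])
        assert abs(steps.var() - v) / v < 0.05

    def test_columns_use_independent_streams(self):
        sched = generate_true_probability_walk(500, seed=4)
        r = np.corrcoef(np.diff(sched.true_prob, axis=0).T)
        off = r[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.15)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            generate_true_probability_walk(0, seed=1)

    def test_same_seed_reproduces_exactly(self):
        a = generate_true_probability_walk(100, seed=5)
        b = generate_true_probability_walk(100, seed=5)
        assert np.array_equal(a.true_prob, b.true_prob)


class TestSessionStructure:
    def test_condition_counts_and_magnitudes(self, skeleton):
        assert len(skeleton) == 180
        assert skeleton["condition"].value_counts().to_dict() == {1: 60, 2: 60,
                                                                  3: 60}
        mags = skeleton[["mag_1", "mag_2", "mag_3"]].to_numpy()
        assert mags.min() >= 1 and mags.max() <= 100

    def test_condition3_second_magnitudes_are_fifty(self):
        opts, mags = second_phase_options(3, 2, [17, 80, 44])
        assert opts == [1, 3] and mags == [50, 50]

    def test_condition2_second_magnitudes_carry_over(self):
        opts, mags = second_phase_options(2, 1, [17, 80, 44])
        assert opts == [2, 3] and mags == [80, 44]

    def test_event_jitter_within_bounds(self, skeleton):
        onsets = np.sort(skeleton[["t_dec1", "t_fb1", "t_foregone", "t_dec2",
                                   "t_fb2"]].to_numpy().ravel())
        onsets = onsets[~np.isnan(onsets)]
        gaps = np.diff(onsets)
        assert gaps.min() >= 2.5 and gaps.max() <= 5.5

    def test_event_phases_match_condition(self, skeleton):
        c1 = skeleton["condition"] == 1
        assert skeleton.loc[c1, "t_foregone"].notna().all()
        assert skeleton.loc[c1, "t_dec2"].isna().all()
        assert skeleton.loc[~c1, "t_dec2"].notna().all()
        assert skeleton.loc[~c1, "t_foregone"].isna().all()

    def test_condition_order_differs_across_seeds(self, schedule):
        a = generate_session(schedule, seed=1)["condition"]
        b = generate_session(schedule, seed=2)["condition"]
        assert not np.array_equal(a, b)

    def test_schedule_length_mismatch_raises(self, schedule):
        with pytest.raises(ValueError):
            generate_session(schedule, SessionConfig(n_trials_per_condition=50))


class TestSimulatedAgent:
    def test_near_deterministic_softmax_picks_best(self, skeleton, schedule,
                                                   small_grid):
        params = cb.ChoiceParams(6000, 3000, 4000)
        sess = simulate_agent(skeleton, schedule, params, "optimal",
                              seed=1, grid=small_grid)
        est = cb.run_learner(sess, "optimal", grid=small_grid)
        mags = sess[["mag_1", "mag_2", "mag_3"]].to_numpy()
        v = subjective_values(est.p_hat, mags, params)
        best = np.argmax(v, axis=1) + 1
        assert (sess["first_choice"] == best).mean() >= 0.99

    def test_zero_params_choose_uniformly(self, skeleton, schedule, small_grid):
        sess = simulate_agent(skeleton, schedule, cb.ChoiceParams(0, 0, 0),
                              "optimal", seed=2, grid=small_grid)
        freqs = sess["first_choice"].value_counts(normalize=True)
        # binomial 3 sigma around 1/3 with n=180
        assert np.all(np.abs(freqs - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 180))

    def test_choice_frequencies_match_softmax(self):
        # fixed values via a non-learning agent and constant magnitudes
        config = SessionConfig(n_trials_per_condition=3334)
        sched = generate_true_probability_walk(config.n_trials, 0.0, seed=3)
        skel = generate_session(sched, config, seed=3)
        skel[["mag_1", "mag_2", "mag_3"]] = [80, 50, 20]
        params = cb.ChoiceParams(0, 2, 0)
        sess = simulate_agent(skel, sched, params, "rescorla_wagner",
                              seed=4, alpha_chosen=0.0, alpha_unchosen=0.0)
        expected = choice_probabilities(
            subjective_values([0.5, 0.5, 0.5], [80, 50, 20], params))
        freqs = np.array([(sess["first_choice"] == s).mean() for s in (1, 2, 3)])
        se = np.sqrt(expected * (1 - expected) / len(sess))
        assert np.all(np.abs(freqs - expected) <= 3 * se)

    def test_unknown_variant_rejected(self, skeleton, schedule):
        with pytest.raises(ValueError):
            simulate_agent(skeleton, schedule, cb.ChoiceParams(1, 1, 1),
                           "q_learning")

    def test_outcome_rate_tracks_true_probability(self, schedule, skeleton,
                                                  small_grid):
        sess = simulate_agent(skeleton, schedule, cb.ChoiceParams(6, 3, 4),
                              "optimal", seed=5, grid=small_grid)
        for s in (1, 2, 3):
            p = schedule.true_prob[:, s - 1]
            rate = sess[f"outcome_{s}"].mean()
            sigma = np.sqrt(np.sum(p * (1 - p))) / len(p)
            assert abs(rate - p.mean()) <= 3 * sigma

    def test_same_seed_reproduces_session(self, skeleton, schedule, small_grid):
        kw = dict(params=cb.ChoiceParams(6, 3, 4), learner_variant="optimal",
                  seed=6, grid=small_grid)
        a = simulate_agent(skeleton, schedule, **kw)
        b = simulate_agent(skeleton, schedule, **kw)
        pd.testing.assert_frame_equal(a, b)


class TestScheduleSelection:
    def test_singleton_candidate_returned(self, small_grid):
        sel = select_decorrelated_schedule(1, learner_config=small_grid,
                                           threshold=1.0, seed=1)
        direct_seed = int(np.random.SeedSequence(1).generate_state(1)[0] % 2**31)
        direct = generate_true_probability_walk(180, seed=direct_seed)
        assert np.array_equal(sel.true_prob, direct.true_prob)

    def test_unreachable_threshold_reports_best(self, small_grid):
        with pytest.raises(RuntimeError, match=r"best max \|r\|"):
            select_decorrelated_schedule(2, learner_config=small_grid,
                                         threshold=1e-6, seed=2)

    def test_many_candidates_decorrelate(self, small_grid):
        sel = select_decorrelated_schedule(12, learner_config=small_grid,
                                           threshold=0.45, seed=3)
        assert sel.true_prob.shape == (180, 3)


class TestSessionIO:
    def test_roundtrip_preserves_data(self, agent_session, tmp_path):
        path = tmp_path / "sess.tsv"
        write_session_tsv(agent_session, path)
        back = read_session_tsv(path)
        for col in ("condition", "first_choice", "outcome_1", "mag_1"):
            assert np.array_equal(back[col], agent_session[col])
        # missing second decisions survive as NaN
        c1 = back["condition"] == 1
        assert back.loc[c1, "second_choice"].isna().all()
        assert np.array_equal(back.loc[~c1, "second_choice"],
                              agent_session.loc[~c1, "second_choice"])

    def test_yaml_config(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_trials_per_condition: 10\nmagnitude_range: [1, 50]\n")
        cfg = SessionConfig.from_yaml(p)
        assert cfg.n_trials == 30 and cfg.magnitude_range == (1, 50)
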