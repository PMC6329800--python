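"""RL model family: update rules, likelihood, fitting, model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsrpe import rl, task


@pytest.fixture
def state():
    return rl.ModelState(rl.ModelSpec(variant="F-DW-Dec", eta=0.5, beta=2.0,
                                      phi=0.5, omega=0.9))


class TestStimulusValue:
    def test_uniform_values_give_half(self, state):
        assert state.stimulus_value((0, 1, 0)) == pytest.approx(0.5)

    def test_degenerate_weight_selects_color_value(self, state):
        state.w = np.array([1.0, 0.0, 0.0])
        state.V[0, 0] = 0.8
        assert state.stimulus_value((0, 0, 0)) == pytest.approx(0.8)

    def test_weighted_sum_hand_value(self, state):
        state.w = np.array([0.5, 0.25, 0.25])
        state.V[0, 0], state.V[1, 1], state.V[2, 0] = 0.8, 0.4, 0.4
        assert state.stimulus_value((0, 1, 0)) == pytest.approx(0.6)

    def test_feature_selective_uses_color_only(self):
        s = rl.ModelState(rl.ModelSpec(variant="F-S"))
        s.V[0, 1] = 0.9
        s.V[1, :] = 0.1  # location values must be ignored
        assert s.stimulus_value((1, 0, 0)) == pytest.approx(0.9)

    def test_unknown_feature_id_rejected(self, state):
        with pytest.raises(rl.DataError):
            state.stimulus_value((2, 0, 0))


class TestChoiceProbabilities:
    def test_zero_beta_gives_half(self):
        s = rl.ModelState(rl.ModelSpec(variant="F-NS", beta=0.0))
        s.V[0, 0] = 0.9
        p = s.choice_probabilities(((0, 0, 0), (1, 1, 1)))
        assert p == pytest.approx([0.5, 0.5])

    def test_closed_form_softmax_value(self):
        # V = (0.75, 0.25), beta = 3.55 -> P = 1/(1+exp(-3.55*0.5))
        s = rl.ModelState(rl.ModelSpec(variant="F-S", beta=3.55))
        s.V[0, 0], s.V[0, 1] = 0.75, 0.25
        p = s.choice_probabilities(((0, 0, 0), (1, 1, 1)))
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-3.55 * 0.5)))
        assert p.sum() == pytest.approx(1.0)

    @given(beta=st.floats(0.0, 20.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_equal_values_symmetric_for_any_beta(self, beta):
        s = rl.ModelState(rl.ModelSpec(variant="F-NS", beta=beta))
        p = s.choice_probabilities(((0, 0, 0), (1, 1, 1)))
        assert p[0] == pytest.approx(0.5)


class TestUpdate:
    def test_rpe_is_reward_minus_value(self, state):
        state.w = np.array([1.0, 0.0, 0.0])
        state.V[0, 0] = 0.75
        rpe = state.update((0, 0, 0), 1)
        assert rpe == pytest.approx(0.25)

    def test_frozen_parameters_leave_state_unchanged(self):
        s = rl.ModelState(rl.ModelSpec(variant="F-DW-Dec", eta=0.0, phi=0.0,
                                       omega=1.0))
        V0, w0 = s.V.copy(), s.w.copy()
        rpe = s.update((0, 1, 0), 1)
        assert rpe == pytest.approx(0.5)
        np.testing.assert_allclose(s.V, V0)
        np.testing.assert_allclose(s.w, w0)

    def test_nonselective_update_hand_iteration(self):
        # F-NS, eta=0.5, all V at 0.5, R=1 -> RPE=0.5, chosen features -> 0.75
        s = rl.ModelState(rl.ModelSpec(variant="F-NS", eta=0.5))
        rpe = s.update((0, 1, 1), 1)
        assert rpe == pytest.approx(0.5)
        assert s.V[0, 0] == pytest.approx(0.75)
        assert s.V[1, 1] == pytest.approx(0.75)
        assert s.V[2, 1] == pytest.approx(0.75)
        assert s.V[0, 1] == pytest.approx(0.5)  # nonchosen untouched (no decay)

    def test_decay_pulls_nonchosen_toward_prior(self):
        s = rl.ModelState(rl.ModelSpec(variant="F-Dec", eta=0.0, omega=0.8))
        s.V[0, 1] = 1.0
        s.update((0, 0, 0), 1)
        assert s.V[0, 1] == pytest.approx(0.8 * 1.0 + 0.2 * 0.5)

    def test_invalid_reward_rejected(self, state):
        with pytest.raises(rl.DataError):
            state.update((0, 0, 0), 2)


class TestDimensionWeights:
    def test_equal_predictiveness_is_fixed_point(self, state):
        state.V[:, 0] = 0.7
        state.V[:, 1] = 0.3
        state.update_dimension_weights()
        np.testing.assert_allclose(state.w, np.full(3, 1 / 3))

    def test_full_rate_jumps_to_predictive_dimension(self):
        s = rl.ModelState(rl.ModelSpec(variant="F-DW", phi=1.0))
        s.V[0, 0] = 0.9  # only color separates its feature values
        s.update_dimension_weights()
        np.testing.assert_allclose(s.w, [1.0, 0.0, 0.0])

    def test_half_rate_hand_arithmetic(self):
        s = rl.ModelState(rl.ModelSpec(variant="F-DW", phi=0.5))
        # engineer predictiveness shares (0.8, 0.1, 0.1)
        s.V[0, 0] = 0.5 + 0.8
        s.V[1, 0] = 0.5 + 0.1
        s.V[2, 0] = 0.5 + 0.1
        s.update_dimension_weights()
        np.testing.assert_allclose(s.w, [0.56666667, 0.21666667, 0.21666667],
                                   atol=1e-8)

    def test_weights_stay_normalized_under_random_updates(self, state):
        rng = np.random.default_rng(0)
        for _ in range(200):
            state.update(tuple(rng.integers(0, 2, 3)), int(rng.integers(2)))
            assert state.w.sum() == pytest.approx(1.0)
            assert (state.w >= 0).all()
            assert ((state.V >= 0) & (state.V <= 1)).all()


class TestLikelihood:
    def test_zero_beta_gives_t_log2(self, behavior_session):
        spec = rl.ModelSpec(variant="F-NS", beta=0.0)
        nll = rl.negative_log_likelihood(spec, behavior_session)
        assert nll == pytest.approx(behavior_session.n_trials * np.log(2))

    def test_kernel_matches_reference_state_stepping(self, reference_spec,
                                                     behavior_session):
        """numba kernel and pure-Python ModelState agree trial by trial."""
        trace = rl.rpe_trace(reference_spec, behavior_session)
        state = rl.ModelState(reference_spec)
        codes = task._chosen_features_codes(behavior_session.trials)
        nll_ref = 0.0
        for t in range(behavior_session.n_trials):
            chosen = tuple(codes[t])
            other = tuple(1 - codes[t])
            p = state.choice_probabilities((chosen, other))[0]
            nll_ref -= np.log(p)
            v = state.stimulus_value(chosen)
            rpe = state.update(chosen, int(behavior_session.trials["rewarded"][t]))
            assert trace["V_chosen"][t] == pytest.approx(v, abs=1e-12)
            assert trace["rpe"][t] == pytest.approx(rpe, abs=1e-12)
            assert trace["p_choice"][t] == pytest.approx(p, abs=1e-12)
        nll = rl.negative_log_likelihood(reference_spec, behavior_session)
        assert nll == pytest.approx(nll_ref, abs=1e-9)

    def test_rpe_bounded_and_shrinking(self, reference_spec, behavior_session):
        trace = rl.rpe_trace(reference_spec, behavior_session)
        assert trace["rpe"].between(-1, 1).all()
        # within long blocks |RPE| declines on average from early to late
        mag = trace.assign(mag=trace["rpe"].abs())
        early = mag[mag["trial"] < 5].groupby("block")["mag"].mean()
        late = mag[mag["trial"] >= 20].groupby("block")["mag"].mean()
        common = early.index.intersection(late.index)
        assert (early[common] - late[common]).mean() > 0

    def test_generating_model_beats_mismatched_variant(self, reference_spec,
                                                       behavior_session):
        nll_true = rl.negative_log_likelihood(reference_spec, behavior_session)
        nll_fs = rl.negative_log_likelihood(
            rl.ModelSpec(variant="F-NS", eta=0.22, beta=3.55),
            behavior_session)
        assert nll_true < nll_fs


class TestFitting:
    def test_recovery_two_parameter_model(self):
        gen = rl.ModelSpec(variant="F-NS", eta=0.3, beta=4.0)
        cfg = task.TaskConfig()
        sessions = [task.generate_session(cfg, rl.RLAgent(gen), seed=50 + i,
                                          n_blocks=9, session_id=i)
                    for i in range(10)]
        fit = rl.fit_mle(rl.ModelSpec(variant="F-NS"), sessions, seed=0)
        assert abs(fit.spec.eta - 0.3) < 0.05
        assert abs(fit.spec.beta - 4.0) / 4.0 < 0.15

    def test_fit_is_seed_deterministic(self, behavior_session):
        a = rl.fit_mle(rl.ModelSpec(variant="F-Dec"), behavior_session, seed=5)
        b = rl.fit_mle(rl.ModelSpec(variant="F-Dec"), behavior_session, seed=5)
        assert a.nll == b.nll
        assert a.spec == b.spec

    def test_aic_formula_and_ranking(self):
        fits = [rl.ModelFit(spec=rl.ModelSpec(variant="F-DW-Dec"), nll=100.0,
                            n_trials=500, seed=0),
                rl.ModelFit(spec=rl.ModelSpec(variant="F-NS"), nll=100.0,
                            n_trials=500, seed=0)]
        assert fits[0].aic == pytest.approx(208.0)
        table = rl.compare_models(fits)
        # equal NLL: the 2-parameter model wins on AIC
        assert table.iloc[0]["variant"] == "F-NS"
        assert table.iloc[0]["aic_best"]

    def test_compare_models_rejects_mixed_data(self):
        fits = [rl.ModelFit(spec=rl.ModelSpec(variant="F-NS"), nll=10.0,
                            n_trials=100, seed=0),
                rl.ModelFit(spec=rl.ModelSpec(variant="F-S"), nll=10.0,
                            n_trials=120, seed=0)]
        with pytest.raises(rl.DataError):
            rl.compare_models(fits)


class TestCrossValidation:
    def test_random_choices_give_chance_test_likelihood(self):
        # value-blind behavior: fitted beta -> 0, so every held-out trial is
        # predicted at 0.5 and test LL per trial ~ -ln 2
        cfg = task.TaskConfig()
        s = task.generate_session(cfg, task.RandomAgent(), seed=3,
                                  n_blocks=10)
        cv = rl.cross_validate(rl.ModelSpec(variant="F-NS"), s, reps=3,
                               seed=2, n_starts=2)
        per_trial = cv["test_ll"] / cv["n_test_trials"]
        assert np.allclose(per_trial, -np.log(2), atol=0.02)

    def test_single_split_reproducible(self, behavior_session):
        a = rl.cross_validate(rl.ModelSpec(variant="F-NS"), behavior_session,
                              reps=1, seed=9, n_starts=1)
        b = rl.cross_validate(rl.ModelSpec(variant="F-NS"), behavior_session,
                              reps=1, seed=9, n_starts=1)
        assert a["test_ll"][0] == b["test_ll"][0]

    def test_too_few_blocks_rejected(self, behavior_session):
        import pandas as pd
        sub = behavior_session.trials[behavior_session.trials["block"] < 2]
        small = task.SessionBehavior(trials=sub.reset_index(drop=True),
                                     rewarded_colors={0: "c1", 1: "c2"})
        with pytest.raises(rl.DataError):
            rl.cross_validate(rl.ModelSpec(variant="F-NS"), small, reps=1)
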