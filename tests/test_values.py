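"""Subjective-value model: closed forms, softmax, likelihood, latents."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aactask import (
    Choice,
    Condition,
    Gamble,
    SubjectParams,
    choice_probs,
    generate_session,
    negative_log_likelihood,
    posterior_no_see,
    subjective_p,
    trial_latents,
    values_apap,
    values_apav,
)
from aactask.cohort import simulate_subject
from aactask.task import CHOICE_ORDER
from aactask.values import stage2_policy, value_grids


class TestSubjectiveP:
    @pytest.mark.parametrize(
        "threat, n, j, expected",
        [(1.0, 12, 3.7, 1.0), (0.5, 6, 1.0, 0.25), (0.25, 12, 2.0, 1 / 16)],
    )
    def test_examples(self, threat, n, j, expected):
        assert subjective_p(threat, n, j) == pytest.approx(expected)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            subjective_p(0.5, 6, 0.0)


class TestPosteriorNoSee:
    @pytest.mark.parametrize("a, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 1 / 3)])
    def test_examples(self, a, expected):
        assert posterior_no_see(a) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_matches_construction(self, a):
        k = posterior_no_see(a)
        assert 0.0 <= k <= 1.0
        assert k == pytest.approx((a / 2) / (1 - a / 2))

    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    def test_monte_carlo_reveal_oracle(self, a):
        """Simulate plant -> activate -> 50% reveal and condition on no-see."""
        rng = np.random.default_rng(int(a * 1000))
        n = 1_000_000
        activated = rng.random(n) < a
        seen = activated & (rng.random(n) < 0.5)
        k_emp = activated[~seen].mean()
        k = posterior_no_see(a)
        se = np.sqrt(k * (1 - k) / (~seen).sum())
        assert abs(k_emp - k) < 3 * se


class TestActionValues:
    def test_apav_closed_forms_half_six(self, default_params):
        av = values_apav(Gamble(0.5, 6), default_params)
        assert av.v_accept_nobomb == pytest.approx(1.5)
        assert av.v_explore == pytest.approx(1.0)
        assert av.v_reject_bomb == 0.0
        assert av.k == pytest.approx(1 / 7)

    def test_apav_reject_always_zero(self, default_params):
        for g in [Gamble(1 / 6, 2), Gamble(1.0, 12), Gamble(0.5, 8)]:
            assert values_apav(g, default_params).v_reject_bomb == 0.0

    def test_apap_certain_bomb(self, default_params):
        av = values_apap(Gamble(1.0, 12, Condition.APAP), default_params)
        assert av.v_reject_bomb == pytest.approx(12.0)  # V(Bomb)
        assert av.v_accept_nobomb == pytest.approx(0.0)  # V(NoBomb)

    def test_apap_symmetric_gamble(self, default_params):
        av = values_apap(Gamble(1.0, 6, Condition.APAP), default_params)
        assert av.a == 0.5
        assert av.v_accept_nobomb == av.v_reject_bomb == pytest.approx(3.0)

    def test_apap_explore_closed_form_half_six(self, default_params):
        # 0.125*6 + 0.875*max(36/7, 6/7) - 2 = 3.25
        av = values_apap(Gamble(0.5, 6, Condition.APAP), default_params)
        assert av.v_explore == pytest.approx(3.25)

    def test_defaults_recover_objective_argmax(self, default_params):
        """Default parameters + hard argmax = the objective optimal policy."""
        from aactask import ev_true

        for cond in Condition:
            V, _, _, _ = value_grids(cond, default_params)
            # accept value equals the objective Eq-based value everywhere
            for r in range(6):
                for c in range(6):
                    g = Gamble((r + 1) / 6, 2 * (c + 1), cond)
                    if cond is Condition.APAV:
                        assert V[r, c, 0] == pytest.approx(ev_true(g))


class TestChoiceProbs:
    def test_equal_values_uniform(self):
        np.testing.assert_allclose(choice_probs([2.0, 2.0, 2.0], 5.0), 1 / 3)

    def test_beta_zero_uniform(self):
        np.testing.assert_allclose(choice_probs([10.0, -3.0, 0.5], 0.0), 1 / 3)

    def test_frozen_high_precision_oracle(self):
        # independent 30-digit softmax evaluation of values (1.5, 0, 1), beta=1
        expected = [0.5465493872661796, 0.12195165230972886, 0.3314989604240915]
        np.testing.assert_allclose(choice_probs([1.5, 0.0, 1.0], 1.0), expected,
                                   rtol=1e-12)

    def test_overflow_safe(self):
        p = choice_probs([1000.0, 0.0, 999.0], 10.0)
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0)
        assert p[0] > 0.999

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.floats(0.0, 10.0),
        st.floats(-20, 20),
    )
    @settings(max_examples=100, derandomize=True)
    def test_simplex_and_shift_invariance(self, vals, beta, shift):
        p = choice_probs(vals, beta)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()
        shifted = choice_probs([v + shift for v in vals], beta)
        np.testing.assert_allclose(p, shifted, atol=1e-9)

    def test_exploration_bonus_monotonicity(self, default_params):
        """Larger w strictly raises p(explore) wherever entropy is positive."""
        for cond in Condition:
            lo, _, _, u = value_grids(cond, default_params.replace(w=0.5))
            hi, _, _, _ = value_grids(cond, default_params.replace(w=1.5))
            p_lo = choice_probs(lo, 2.0)[..., 2]
            p_hi = choice_probs(hi, 2.0)[..., 2]
            positive_u = u > 0
            assert np.all(p_hi[positive_u] > p_lo[positive_u])

    def test_loss_aversion_monotonicity(self, default_params):
        """More negative f weakly lowers p(accept) on every Ap/Av gamble."""
        mild, _, _, _ = value_grids(Condition.APAV, default_params.replace(f=-12.0))
        harsh, _, _, _ = value_grids(Condition.APAV, default_params.replace(f=-30.0))
        p_mild = choice_probs(mild, 2.0)[..., 0]
        p_harsh = choice_probs(harsh, 2.0)[..., 0]
        assert np.all(p_harsh <= p_mild + 1e-12)


class TestNegativeLogLikelihood:
    @staticmethod
    def _completed_session(params, seed=0, n_reps=2):
        session = generate_session(n_reps=n_reps, seed=seed)
        return simulate_subject(params, session, seed=seed + 1)

    def test_uniform_model_gives_n_log3(self, default_params):
        trials = self._completed_session(default_params).head(30)
        trials = trials[trials["condition"] == "APAV"]
        nll = negative_log_likelihood(trials, default_params.replace(beta=0.0))
        assert nll == pytest.approx(len(trials) * np.log(3))

    def test_matches_direct_softmax_sum(self, default_params):
        params = default_params.replace(w=0.8, beta=1.7)
        trials = self._completed_session(params, seed=3)
        apav = trials[trials["condition"] == "APAV"]
        expected = 0.0
        for _, t in apav.iterrows():
            g = Gamble(t["env_threat_level"] / 6, int(t["n_tokens"]))
            p = choice_probs(values_apav(g, params), params.beta)
            idx = [c.value for c in CHOICE_ORDER].index(t["stage1_choice"])
            expected -= np.log(p[idx])
        assert negative_log_likelihood(apav, params) == pytest.approx(expected)

    def test_generating_params_beat_perturbed(self, default_params):
        """Simulation oracle: NLL is lower at the generating parameters."""
        gen = default_params.replace(f=-10.0, w=1.0, beta=2.0)
        pert = gen.replace(f=-20.0, w=0.0)
        wins = 0
        for seed in range(30):
            trials = self._completed_session(gen, seed=seed, n_reps=2)
            apav = trials[trials["condition"] == "APAV"]
            if negative_log_likelihood(apav, gen) < negative_log_likelihood(apav, pert):
                wins += 1
        assert wins >= 25

    def test_empty_dataset_rejected(self, default_params):
        with pytest.raises(ValueError):
            negative_log_likelihood(pd.DataFrame(columns=["condition"]), default_params)

    def test_mixed_conditions_rejected(self, default_params):
        trials = self._completed_session(default_params)
        with pytest.raises(ValueError):
            negative_log_likelihood(trials, default_params)


class TestStage2Policy:
    def test_seen_bomb_forces_reject(self, default_params):
        for cond in Condition:
            assert (
                stage2_policy(cond, 0.3, 6, default_params, saw_bomb=True)
                is Choice.REJECT_BOMB
            )

    def test_apav_null_reveal_accepts_when_worth_it(self, default_params):
        # a=0.25 -> k=1/7: k*f + (1-k)*n = 24/7 > 0 -> accept
        assert (
            stage2_policy(Condition.APAV, 0.25, 6, default_params, saw_bomb=False)
            is Choice.ACCEPT_NOBOMB
        )

    def test_apav_null_reveal_rejects_when_still_too_risky(self, default_params):
        assert (
            stage2_policy(Condition.APAV, 0.99, 2, default_params, saw_bomb=False)
            is Choice.REJECT_BOMB
        )

    def test_apap_tie_resolves_to_bomb_guess(self, default_params):
        # a=1 -> k=1 exactly: stage-2 accept value is i, reject value is n;
        # with i=n the two are equal and the strict > keeps the "bomb" guess
        params = default_params.replace(i=6.0)
        assert posterior_no_see(1.0) == 1.0
        assert (
            stage2_policy(Condition.APAP, 1.0, 6, params, saw_bomb=False)
            is Choice.REJECT_BOMB
        )


class TestTrialLatents:
    @staticmethod
    def _latents(params, seed=5):
        session = generate_session(n_reps=1, seed=seed)
        trials = simulate_subject(params, session, seed=seed + 1)
        return trials, trial_latents(trials, params)

    def test_value_difference_of_explored_trial(self, default_params):
        trials, lat = self._latents(default_params.replace(beta=0.5))
        explored = lat[lat["stage1_choice"] == "EXPLORE"]
        row = explored.iloc[0]
        assert row["v_chosen"] == pytest.approx(row["v_explore"])
        others = max(row["v_accept_nobomb"], row["v_reject_bomb"])
        assert row["v_best_unchosen"] == pytest.approx(others)
        assert row["value_difference"] == pytest.approx(row["v_chosen"] - others)

    def test_apav_reject_has_zero_chosen_value(self, default_params):
        trials, lat = self._latents(default_params.replace(f=-30.0, beta=1.0))
        rej = lat[(lat["condition"] == "APAV") & (lat["stage1_choice"] == "REJECT_BOMB")]
        assert len(rej) > 0
        assert (rej["v_chosen"] == 0).all()
        assert (rej["rejected"] == 1).all()

    def test_argmax_agent_never_negative_difference(self, default_params):
        params = default_params.replace(beta=1e6)
        trials, lat = self._latents(params, seed=9)
        assert (lat["value_difference"] >= -1e-9).all()

    def test_latents_cover_both_conditions(self, default_params):
        trials, lat = self._latents(default_params)
        assert set(lat["condition"]) == {"APAV", "APAP"}
        assert len(lat) == len(trials)
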