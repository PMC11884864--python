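"""Model family: value updates, choice rule, likelihood, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn.models import (
    ModelSpec,
    Params,
    candidate_specs,
    choice_probability,
    session_loglik,
    simulate_subject,
    trial_latents,
    update_values,
)
from revlearn.task import TaskConfig

from conftest import make_session

ALL_SPECS = candidate_specs()


def replay_loglik(session, params, spec):
    """Straight-line reference recursion, independent of the compiled path."""
    q = [0.0, 0.0]
    beta = params.beta if spec.sensitivity_kind == "choice" else 1.0
    ll = 0.0
    for t in session.trials:
        if t.choice is None:
            continue
        z = beta * (q[t.choice] - q[1 - t.choice])
        ll += -math.log1p(math.exp(-z)) if z > -30 else z
        o = t.feedback_sign
        if spec.sensitivity_kind == "choice":
            r = float(o)
        else:
            r = params.rho_win if o > 0 else params.rho_loss
        a = params.alpha_win if o > 0 else params.alpha_loss
        c, u = t.choice, 1 - t.choice
        q[c] += a * (r - q[c])
        if spec.update_rule == "DU":
            q[u] += a * (-r - q[u])
    return ll


class TestUpdateValues:
    def test_double_update_moves_both_options(self):
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=0.5, rho_win=2.0, rho_loss=-1.0)
        assert update_values((0, 0), 0, "win", p) == (1.0, -1.0)

    def test_single_update_leaves_unchosen_unchanged(self):
        spec = ModelSpec.from_code("SU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=0.5, rho_win=2.0, rho_loss=-1.0)
        assert update_values((0, 0), 0, "win", p) == (1.0, 0.0)

    def test_full_learning_rate_jumps_to_outcome_value(self):
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=1 - 1e-12, rho_win=2.0, rho_loss=-1.0)
        q = update_values((0.37, -0.9), 1, "loss", p)
        assert q[1] == pytest.approx(-1.0)
        assert q[0] == pytest.approx(1.0)

    def test_two_learning_rates_split_by_valence(self):
        spec = ModelSpec.from_code("SU-2rho-2alpha")
        p = Params.from_natural(spec, alpha_win=0.8, alpha_loss=0.2,
                                rho_win=1.0, rho_loss=-1.0)
        assert update_values((0, 0), 0, "win", p)[0] == pytest.approx(0.8)
        assert update_values((0, 0), 0, "loss", p)[0] == pytest.approx(-0.2)


class TestChoiceProbability:
    def test_equal_values_give_chance(self, mid_params):
        assert choice_probability((0.4, 0.4), mid_params) == pytest.approx(0.5)

    def test_logistic_of_value_difference(self, mid_params):
        # beta fixed to 1 for reinforcement-sensitivity models
        expected = 1.0 / (1.0 + math.exp(-4.0))
        assert choice_probability((2.0, -2.0), mid_params) == pytest.approx(expected)

    def test_symmetry(self, mid_params):
        p = choice_probability((1.3, -0.2), mid_params)
        assert choice_probability((-0.2, 1.3), mid_params) == pytest.approx(1 - p)

    def test_beta_sharpens_choice(self):
        spec = ModelSpec.from_code("DU-beta-1alpha")
        q = (0.6, 0.1)
        probs = [
            choice_probability(q, Params.from_natural(spec, alpha=0.5, beta=b))
            for b in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))
        assert all(p > 0.5 for p in probs)


class TestTransforms:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.code)
    def test_round_trip_to_machine_precision(self, spec):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(0, 2, spec.n_params)
            back = Params.from_transformed(spec, x).to_transformed()
            np.testing.assert_allclose(back, x, rtol=0, atol=1e-12)

    def test_parameter_counts(self):
        assert {s.n_params for s in ALL_SPECS} == {2, 3, 4}
        assert ModelSpec.from_code("DU-2rho-1alpha").param_names == (
            "alpha", "rho_win", "rho_loss"
        )
        assert ModelSpec.random().n_params == 0


class TestSessionLoglik:
    @pytest.mark.parametrize("code", ["DU-2rho-1alpha", "SU-2rho-1alpha",
                                      "DU-beta-1alpha", "SU-1rho-2alpha",
                                      "DU-2rho-2alpha"])
    def test_matches_replay_oracle(self, code, mid_params, task_config):
        spec = ModelSpec.from_code(code)
        rng = np.random.default_rng(3)
        for i in range(5):
            session = simulate_subject(mid_params, config=task_config, seed=i)
            # knock out a few trials to exercise missing handling
            for k in rng.choice(len(session.trials), size=4, replace=False):
                t = session.trials[k]
                session.trials[k] = t.__class__(
                    **{**t.__dict__, "choice": None, "correct": None,
                       "feedback_sign": None, "feedback_value": None}
                )
            p = Params.from_transformed(spec, rng.normal(0, 1, spec.n_params))
            assert session_loglik(session, p) == pytest.approx(
                replay_loglik(session, p, spec), abs=1e-10
            )

    def test_zero_sensitivities_give_chance_likelihood(self):
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=0.5, rho_win=0.0, rho_loss=0.0)
        session = make_session([0, 1, 0, None, 1], [1, -1, 1, None, -1])
        assert session_loglik(session, p) == pytest.approx(4 * math.log(0.5))

    def test_loglik_is_negative_and_bounded(self, mid_params, task_config):
        session = simulate_subject(mid_params, config=task_config, seed=9)
        ll = session_loglik(session, mid_params)
        assert ll <= 0
        lat = trial_latents(session, mid_params)
        assert ll >= len(session.trials) * math.log(lat["p_choice"].min())

    def test_empty_session_rejected(self, mid_params):
        session = make_session([None, None], [None, None])
        with pytest.raises(ValueError):
            session_loglik(session, mid_params)


class TestValueBoundedness:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        alpha=st.floats(0.01, 0.99),
        rho_win=st.floats(0.1, 5.0),
        rho_loss=st.floats(-5.0, -0.1),
        du=st.booleans(),
        seed=st.integers(0, 10_000),
    )
    def test_values_stay_within_sensitivity_bounds(self, alpha, rho_win,
                                                   rho_loss, du, seed):
        code = ("DU" if du else "SU") + "-2rho-1alpha"
        spec = ModelSpec.from_code(code)
        p = Params.from_natural(spec, alpha=alpha, rho_win=rho_win,
                                rho_loss=rho_loss)
        bound = max(abs(rho_win), abs(rho_loss)) + 1e-12
        rng = np.random.default_rng(seed)
        q = (0.0, 0.0)
        for _ in range(200):
            choice = int(rng.integers(2))
            outcome = "win" if rng.random() < 0.5 else "loss"
            q = update_values(q, choice, outcome, p)
            assert abs(q[0]) <= bound and abs(q[1]) <= bound


class TestSimulation:
    def test_seed_reproducibility(self, mid_params, task_config):
        a = simulate_subject(mid_params, config=task_config, seed=42)
        b = simulate_subject(mid_params, config=task_config, seed=42)
        assert a.choices.tolist() == b.choices.tolist()
        assert a.outcomes.tolist() == b.outcomes.tolist()

    def test_tiny_learning_rate_behaves_like_chance(self, task_config):
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=1e-9, rho_win=2.5, rho_loss=-0.7)
        acc = np.mean([
            np.mean([t.correct for t in
                     simulate_subject(p, config=task_config, seed=i).trials])
            for i in range(200)
        ])
        assert abs(acc - 0.5) < 0.02

    def test_extreme_win_sensitivity_forces_stay_after_win(self, task_config):
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=0.9, rho_win=50.0, rho_loss=-1e-9)
        stays = wins = 0
        for i in range(50):
            s = simulate_subject(p, config=task_config, seed=i)
            ch, out = s.choices, s.outcomes
            prev_win = out[:-1] > 0
            stays += int(np.sum((ch[1:] == ch[:-1]) & prev_win))
            wins += int(np.sum(prev_win))
        assert stays / wins > 0.999

    def test_stay_after_win_exceeds_stay_after_loss(self, mid_params,
                                                    task_config):
        # rho_win > 0 > rho_loss implies win-stay > lose-stay
        sw, sl = [], []
        for i in range(200):
            s = simulate_subject(mid_params, config=task_config, seed=i)
            ch, out = s.choices, s.outcomes
            stay = ch[1:] == ch[:-1]
            prev_win = out[:-1] > 0
            sw.append(stay[prev_win].mean())
            sl.append(stay[~prev_win].mean())
        assert np.mean(sw) > np.mean(sl) + 0.2


class TestTrialLatents:
    def test_first_trial_is_chance_and_not_below(self, mid_params, task_config):
        session = simulate_subject(mid_params, config=task_config, seed=1)
        lat = trial_latents(session, mid_params)
        assert lat.loc[0, "p_choice"] == pytest.approx(0.5)
        assert not lat.loc[0, "below_chance"]  # strictly < 0.5

    def test_full_learning_rate_hand_trace(self):
        # alpha ~ 1: after a win on stimulus 0, Q = (rho_win, -rho_win);
        # the DU counterfactual PE on the next trial follows directly
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=1 - 1e-12, rho_win=2.0,
                                rho_loss=-1.0)
        session = make_session([0, 0, 1], [1, -1, 1])
        lat = trial_latents(session, p)
        assert lat["pe_chosen"].tolist() == pytest.approx([2.0, -1.0 - 2.0,
                                                           2.0 - 1.0])
        assert lat["pe_unchosen"].tolist() == pytest.approx([-2.0, 1.0 + 2.0,
                                                             -2.0 - (-1.0)])

    def test_alternating_against_own_values_flags_below_chance(self):
        # agent repeatedly chooses the option its own values disfavour
        spec = ModelSpec.from_code("DU-2rho-1alpha")
        p = Params.from_natural(spec, alpha=0.6, rho_win=2.0, rho_loss=-1.0)
        # stimulus 0 keeps winning, but the agent switches to 1 every time
        session = make_session([0, 1, 1, 1], [1, -1, -1, -1])
        lat = trial_latents(session, p)
        assert not lat.loc[0, "below_chance"]
        assert lat.loc[1:, "below_chance"].all()

    def test_missing_trials_freeze_values(self, mid_params):
        s_full = make_session([0, 0], [1, 1])
        s_gap = make_session([0, None, 0], [1, None, 1])
        lat_full = trial_latents(s_full, mid_params)
        lat_gap = trial_latents(s_gap, mid_params)
        assert np.isnan(lat_gap.loc[1, "p_choice"])
        assert lat_gap.loc[2, "p_choice"] == pytest.approx(
            lat_full.loc[1, "p_choice"]
        )
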