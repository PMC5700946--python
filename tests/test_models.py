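"""RL model update rules, choice rules, likelihoods, and simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featlearn.environments import FeatureSpace
from featlearn.models import (
    MODEL_SPECS,
    ModelSpec,
    ParamVector,
    apply_decay,
    choice_prob_feature,
    choice_prob_object,
    encode_trials,
    negative_log_likelihood,
    simulate_agent,
    update_coupled,
    update_uncoupled,
)
from featlearn.tasks import build_exp12_design


class TestSpecs:
    def test_seven_models_defined(self):
        assert len(MODEL_SPECS) == 7
        names = set(MODEL_SPECS)
        assert {"object_uncoupled", "object_coupled", "object_decay",
                "feature_uncoupled", "feature_coupled", "feature_decay",
                "feature_decay_attn"} == names

    def test_coupled_excludes_decay(self):
        with pytest.raises(ValueError):
            ModelSpec("object", "coupled", decay=True)

    def test_attentional_requires_feature_decay(self):
        with pytest.raises(ValueError):
            ModelSpec("object", "uncoupled", decay=True, attentional=True)

    def test_parameter_counts(self):
        assert MODEL_SPECS["object_uncoupled"].n_params() == 4
        assert MODEL_SPECS["object_decay"].n_params() == 5
        assert MODEL_SPECS["feature_uncoupled"].n_params(m=2) == 5
        assert MODEL_SPECS["feature_decay"].n_params(m=2) == 6


class TestElementaryRules:
    def test_uncoupled_updates(self):
        assert update_uncoupled(0.5, 1, 0.2, 0.1) == pytest.approx(0.6)
        assert update_uncoupled(0.5, 0, 0.2, 0.1) == pytest.approx(0.45)

    def test_coupled_updates_opposite_direction(self):
        assert update_coupled(0.5, 1, 0.2, 0.2) == pytest.approx(0.4)
        assert update_coupled(0.5, 0, 0.2, 0.2) == pytest.approx(0.6)

    def test_coupled_symmetric_separation(self):
        v_c = update_uncoupled(0.5, 1, 0.2, 0.2)
        v_u = update_coupled(0.5, 1, 0.2, 0.2)
        assert v_c - v_u == pytest.approx(2 * 0.2 * 0.5)

    def test_decay_toward_half(self):
        assert apply_decay(0.8, 0.1) == pytest.approx(0.77)
        assert apply_decay(0.5, 0.1) == pytest.approx(0.5)

    def test_decay_contracts_monotonically(self):
        v = 0.9
        prev_gap = abs(v - 0.5)
        for _ in range(50):
            v = float(apply_decay(v, 0.2))
            gap = abs(v - 0.5)
            assert gap <= prev_gap
            prev_gap = gap
        assert v == pytest.approx(0.5, abs=1e-4)

    def test_choice_prob_object_values(self):
        assert choice_prob_object(0.5, 0.5, 0.1) == pytest.approx(0.5)
        assert choice_prob_object(0.6, 0.4, 0.1) == pytest.approx(
            1 / (1 + np.exp(-2))
        )
        assert choice_prob_object(0.5, 0.5, 0.1, bias=50.0) > 0.999

    def test_choice_prob_feature_reductions(self):
        assert choice_prob_feature([0.5, 0.5], [0.5, 0.5], [5, 5]) == 0.5
        # zero weight on the second feature reduces to the object rule
        p1 = choice_prob_feature([0.7, 0.2], [0.5, 0.9], [10.0, 0.0])
        p2 = choice_prob_object(0.7, 0.5, sigma=0.1)
        assert p1 == pytest.approx(p2)
        # opposite differences cancel with equal weights
        assert choice_prob_feature([0.7, 0.3], [0.5, 0.5], [5, 5]) == pytest.approx(0.5)

    def test_choice_prob_complementarity(self):
        for dv in (-0.3, 0.0, 0.2):
            p_lr = choice_prob_object(0.5 + dv, 0.5, 0.1)
            p_rl = choice_prob_object(0.5, 0.5 + dv, 0.1)
            assert p_lr + p_rl == pytest.approx(1.0)


def _toy_log(rows):
    base = {
        "subject_id": "t",
        "experiment": 1,
        "session": 1,
        "block": 1,
        "schedule_id": "s",
        "reward_left": pd.NA,
        "reward_right": pd.NA,
    }
    out = []
    for i, r in enumerate(rows, start=1):
        rec = dict(base)
        rec.update(trial=i, **r)
        out.append(rec)
    return pd.DataFrame(out)


class TestLikelihood:
    def test_random_guess_closed_form(self):
        space = FeatureSpace(2, 2, 2.0)
        rows = [
            dict(left_object="0-0", right_object="1-1", choice="L",
                 chosen_object="0-0", reward=1)
            for _ in range(50)
        ]
        log = _toy_log(rows)
        spec = MODEL_SPECS["object_uncoupled"]
        # enormous stochasticity: every choice is a coin flip
        params = ParamVector(alpha_rew=0.2, alpha_unr=0.2, sigma=1e9, bias=0.0)
        nll = negative_log_likelihood(log, spec, params, space=space)
        assert nll == pytest.approx(50 * np.log(2), rel=1e-6)

    def test_single_trial_value(self):
        space = FeatureSpace(2, 2, 2.0)
        log = _toy_log(
            [dict(left_object="0-0", right_object="1-1", choice="L",
                  chosen_object="0-0", reward=1)]
        )
        spec = MODEL_SPECS["object_uncoupled"]
        params = ParamVector(alpha_rew=0.2, alpha_unr=0.2, sigma=0.1, bias=2.0)
        # first trial: equal values, bias 2 -> P(L) = logistic(2)
        expected = -np.log(1 / (1 + np.exp(-2.0)))
        nll = negative_log_likelihood(log, spec, params, space=space)
        assert nll == pytest.approx(expected, abs=1e-10)

    def test_shared_feature_rule(self):
        # pair red-square vs red-triangle: only the shape feature updates
        space = FeatureSpace(2, 2, 2.0)
        log = _toy_log(
            [
                dict(left_object="0-0", right_object="0-1", choice="L",
                     chosen_object="0-0", reward=1),
                dict(left_object="0-0", right_object="1-1", choice="L",
                     chosen_object="0-0", reward=1),
            ]
        )
        spec = MODEL_SPECS["feature_uncoupled"]
        params = ParamVector(
            alpha_rew=0.2, alpha_unr=0.2, sigma=0.1, bias=0.0,
            w=np.array([[10.0, 10.0]]),
        )
        nll, per_trial = negative_log_likelihood(
            log, spec, params, space=space, per_trial=True
        )
        # after trial 1, color (feature 0, shared) stays 0.5; shape -> 0.6
        # trial 2 logit = 10*(0.5-0.5) + 10*(0.6-0.5) = 1
        assert per_trial[1] == pytest.approx(-np.log(1 / (1 + np.exp(-1.0))), abs=1e-9)

    def test_update_shared_variant_differs(self):
        space = FeatureSpace(2, 2, 2.0)
        log = _toy_log(
            [
                dict(left_object="0-0", right_object="0-1", choice="L",
                     chosen_object="0-0", reward=1),
                dict(left_object="0-0", right_object="1-0", choice="L",
                     chosen_object="0-0", reward=1),
            ]
        )
        params = ParamVector(
            alpha_rew=0.2, alpha_unr=0.2, sigma=0.1, bias=0.0,
            w=np.array([[10.0, 10.0]]),
        )
        a = negative_log_likelihood(
            log, MODEL_SPECS["feature_uncoupled"], params, space=space
        )
        b = negative_log_likelihood(
            log,
            ModelSpec("feature", "uncoupled", update_shared=True),
            params,
            space=space,
        )
        assert a != pytest.approx(b)

    def test_m1_feature_object_equivalence(self):
        """With one feature the two representations induce equal likelihoods."""
        space = FeatureSpace(1, 3, 2.0)
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(80):
            a, b = rng.choice(3, size=2, replace=False)
            cho = a if rng.random() < 0.5 else b
            rows.append(
                dict(
                    left_object=str(a), right_object=str(b),
                    choice="L" if cho == a else "R",
                    chosen_object=str(cho), reward=int(rng.random() < 0.5),
                )
            )
        log = _toy_log(rows)
        sigma = 0.13
        p_obj = ParamVector(alpha_rew=0.25, alpha_unr=0.15, sigma=sigma, bias=0.1)
        p_fea = ParamVector(
            alpha_rew=0.25, alpha_unr=0.15, sigma=sigma, bias=0.1,
            w=np.array([[1.0 / sigma]]),
        )
        nll_o = negative_log_likelihood(
            log, MODEL_SPECS["object_uncoupled"], p_obj, space=space
        )
        nll_f = negative_log_likelihood(
            log, MODEL_SPECS["feature_uncoupled"], p_fea, space=space
        )
        assert nll_o == pytest.approx(nll_f, abs=1e-9)

    def test_generating_params_beat_mismatched_sigma(self, feature_decay_agent_log):
        log, spec, params = feature_decay_agent_log
        space = FeatureSpace(2, 2, 3.0)
        sub = log.iloc[:100]
        good = negative_log_likelihood(sub, spec, params, space=space)
        worse_params = ParamVector(
            alpha_rew=params.alpha_rew,
            alpha_unr=params.alpha_unr,
            d=params.d,
            sigma=params.sigma * 10,
            bias=params.bias,
            w=np.asarray(params.w) / 10.0,
        )
        bad = negative_log_likelihood(sub, spec, worse_params, space=space)
        assert good < bad


class TestSimulation:
    def test_deterministic_log(self, exp1_design):
        spec = MODEL_SPECS["object_uncoupled"]
        params = ParamVector(alpha_rew=0.2, alpha_unr=0.2, sigma=0.1)
        a = simulate_agent(exp1_design, spec, params, seed=3)
        b = simulate_agent(exp1_design, spec, params, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_bias_forces_left(self, exp1_design):
        spec = MODEL_SPECS["object_uncoupled"]
        # bias must dominate the value term, whose magnitude reaches 1/sigma
        params = ParamVector(alpha_rew=0.2, alpha_unr=0.2, sigma=0.1, bias=30.0)
        log = simulate_agent(exp1_design, spec, params, seed=3)
        assert (log["choice"] == "L").mean() > 0.99

    def test_near_greedy_feature_agent_approaches_ceiling(self):
        # static generalizable schedule: a near-greedy feature-based agent
        # approaches the ceiling of always picking the better pair member
        from featlearn.environments import RewardMatrix
        from featlearn.tasks import build_reversal_design
        import itertools

        d12 = build_exp12_design("generalizable", 0, seed=0)
        mat = RewardMatrix(space=d12.space, p=d12.schedules["Rs"],
                           informative_feature=0)
        design = build_reversal_design(mat, L=10**6, trials_per_session=4000)
        spec = MODEL_SPECS["feature_uncoupled"]
        params = ParamVector(
            alpha_rew=0.3, alpha_unr=0.3, bias=0.0,
            w=np.array([[1e4, 1e4]]),
        )
        log = simulate_agent(design, spec, params, seed=0)
        p = mat.flat_p
        ceiling = np.mean(
            [max(p[i], p[j]) for i, j in itertools.combinations(range(4), 2)]
        )
        mean_reward = log["reward"].iloc[200:].mean()
        se = np.sqrt(0.25 / 3800)
        assert mean_reward > ceiling - 0.02 - 3 * se

    def test_values_bounded_all_models(self, exp1_design):
        # likelihood replay never produces probabilities outside (0,1):
        # implied values stayed inside [0,1]
        space = exp1_design.space
        for name, spec in MODEL_SPECS.items():
            params = ParamVector(
                alpha_rew=1.0, alpha_unr=1.0, d=0.5, sigma=0.05, bias=0.0,
                w=np.array([[12.0, 12.0]]),
                alpha_feature=np.array([1.0, 1.0]) if spec.attentional else None,
            )
            log = simulate_agent(exp1_design, spec, params, seed=1)
            nll, p = negative_log_likelihood(
                log, spec, params, space=space, per_trial=True
            )
            assert np.isfinite(nll)
            assert np.all(np.isfinite(p))


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_incremental_equals_full_replay(seed):
    """The streaming -LL equals recomputing the replay from scratch."""
    space = FeatureSpace(2, 2, 2.0)
    design = build_exp12_design("generalizable", 0, seed=0)
    spec = MODEL_SPECS["feature_decay"]
    params = ParamVector(
        alpha_rew=0.3, alpha_unr=0.2, d=0.03, sigma=0.1,
        w=np.array([[8.0, 8.0]]),
    )
    log = simulate_agent(design, spec, params, seed=seed).iloc[:60]
    total, per_trial = negative_log_likelihood(
        log, spec, params, space=space, per_trial=True
    )
    assert total == pytest.approx(per_trial.sum(), abs=1e-10)
    # replaying any prefix from scratch reproduces the streaming values
    for k in (1, 17, 42):
        prefix = negative_log_likelihood(log.iloc[:k], spec, params, space=space)
        assert prefix == pytest.approx(per_trial[:k].sum(), abs=1e-10)
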