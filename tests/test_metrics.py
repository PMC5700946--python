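"""Behavioral metrics: thresholds, differential responses, estimation fits."""

import numpy as np
import pandas as pd
import pytest

from featlearn.environments import feature_profile
from featlearn.metrics import (
    differential_response,
    estimation_correlation,
    estimation_regression,
    exclusion_threshold,
    performance_curves,
    trend_fit,
)
from featlearn.tasks import build_exp12_design, build_exp34_design


class TestExclusionThreshold:
    @pytest.mark.parametrize(
        "n,expected", [(608, 0.5406), (500, 0.5447), (612, 0.5404)]
    )
    def test_printed_thresholds(self, n, expected):
        assert exclusion_threshold(n) == expected

    def test_closed_form_before_rounding(self):
        n = 1234
        raw = 0.5 + 2 * np.sqrt(0.25 / n)
        assert abs(exclusion_threshold(n) - raw) < 5e-5

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            exclusion_threshold(0)


def _toy_trials(rows, subject="s1", session=1):
    recs = []
    for i, r in enumerate(rows, start=1):
        rec = dict(
            subject_id=subject, experiment=3, session=session, trial=i,
            block=1, schedule_id="static", reward_left=pd.NA,
            reward_right=pd.NA,
        )
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestDifferentialResponse:
    def test_toy_feature_differential_is_one(self, exp3_design):
        # trial 1: choose 0-0, rewarded; trial 2: pair {1-0 (shares feature 1),
        # 2-1 (shares none)}: choose the sharer.
        # trial 3: choose 0-0, unrewarded; trial 4: same pair, choose non-sharer.
        rows = [
            dict(left_object="0-0", right_object="1-1", choice="L",
                 chosen_object="0-0", reward=1),
            dict(left_object="1-0", right_object="2-1", choice="L",
                 chosen_object="1-0", reward=1),
            dict(left_object="0-0", right_object="1-1", choice="L",
                 chosen_object="0-0", reward=0),
            dict(left_object="1-0", right_object="2-1", choice="R",
                 chosen_object="2-1", reward=0),
        ]
        trials = _toy_trials(rows)
        out = differential_response(trials, exp3_design, kind="feature")
        assert out["differential"] == pytest.approx(1.0)
        assert out["n_rewarded"] == 1 and out["n_unrewarded"] == 1

    def test_object_differential_win_stay(self, exp3_design):
        rows = [
            dict(left_object="0-0", right_object="1-1", choice="L",
                 chosen_object="0-0", reward=1),
            dict(left_object="0-0", right_object="2-1", choice="L",
                 chosen_object="0-0", reward=1),
            dict(left_object="0-0", right_object="1-1", choice="L",
                 chosen_object="0-0", reward=0),
            dict(left_object="0-0", right_object="2-1", choice="R",
                 chosen_object="2-1", reward=1),
        ]
        out = differential_response(_toy_trials(rows), exp3_design, kind="object")
        assert out["differential"] == pytest.approx(1.0)

    def test_memoryless_agent_near_zero(self, exp3_design):
        from featlearn.models import MODEL_SPECS, ParamVector, simulate_agent

        # enormous stochasticity: choices independent of history
        spec = MODEL_SPECS["object_uncoupled"]
        params = ParamVector(alpha_rew=0.2, alpha_unr=0.2, sigma=1e9)
        log = simulate_agent(exp3_design, spec, params, seed=0)
        out = differential_response(log, exp3_design, kind="object")
        n = min(out["n_rewarded"], out["n_unrewarded"])
        assert abs(out["differential"]) < 3 * np.sqrt(0.5 / n)

    def test_no_eligible_trials_is_nan(self, exp3_design):
        rows = [
            dict(left_object="0-0", right_object="1-1", choice="L",
                 chosen_object="0-0", reward=1),
        ]
        out = differential_response(_toy_trials(rows), exp3_design, kind="feature")
        assert np.isnan(out["differential"])
        assert out["n_rewarded"] == 0

    def test_win_stay_agent_positive_object_differential(self, exp3_design):
        """Any win-stay agent shows a positive object-based differential."""
        rng = np.random.default_rng(2)
        objs = [exp3_design.space.token(o) for o in exp3_design.used_objects]
        rows = []
        prev_choice, prev_r = None, None
        from featlearn.tasks import sample_pair

        for _ in range(600):
            a, b = sample_pair(exp3_design, rng)
            ta, tb = (
                exp3_design.space.token(a),
                exp3_design.space.token(b),
            )
            if prev_r == 1 and prev_choice in (ta, tb):
                cho = prev_choice
            else:
                cho = ta if rng.random() < 0.5 else tb
            r = int(rng.random() < 0.55)
            rows.append(
                dict(left_object=ta, right_object=tb,
                     choice="L" if cho == ta else "R",
                     chosen_object=cho, reward=r)
            )
            prev_choice, prev_r = cho, r
        out = differential_response(_toy_trials(rows), exp3_design, kind="object")
        assert out["differential"] > 0


class TestEstimationAnalyses:
    def _estimates_from(self, design, values, subject="s1"):
        space = design.space
        rows = []
        for block in (1, 2):
            for obj in design.used_objects:
                idx = np.ravel_multi_index(obj, space.shape)
                rows.append(
                    dict(
                        subject_id=subject, experiment=design.experiment,
                        session=1, estimation_block=block,
                        object=space.token(obj),
                        estimate_percent=values[idx] * 100.0,
                    )
                )
        return pd.DataFrame(rows)

    def test_pure_object_estimates(self, exp3_design):
        est = self._estimates_from(exp3_design, exp3_design.matrix.flat_p)
        reg = estimation_regression(est, exp3_design.matrix)
        assert np.allclose(reg["relative_weight"], 1.0, atol=1e-6)
        assert np.allclose(reg["r_squared"], 1.0)
        corr = estimation_correlation(est, exp3_design.matrix)
        assert np.all(corr["object_flag"] == 1.0)

    def test_pure_feature_estimates(self, exp3_design):
        recon = feature_profile(exp3_design.matrix).estimated.ravel()
        est = self._estimates_from(exp3_design, recon)
        reg = estimation_regression(est, exp3_design.matrix)
        assert np.allclose(reg["relative_weight"], 0.0, atol=1e-6)
        corr = estimation_correlation(est, exp3_design.matrix)
        assert np.all(corr["object_flag"] == 0.0)

    def test_even_mixture_gives_half_weight(self, exp3_design):
        recon = feature_profile(exp3_design.matrix).estimated.ravel()
        mix = 0.5 * exp3_design.matrix.flat_p + 0.5 * recon
        est = self._estimates_from(exp3_design, mix)
        reg = estimation_regression(est, exp3_design.matrix)
        assert np.allclose(reg["relative_weight"], 0.5, atol=1e-6)

    def test_mixture_sweep_flag_crossing(self, exp3_design):
        recon = feature_profile(exp3_design.matrix).estimated.ravel()
        flags = []
        for lam in (0.1, 0.9):
            mix = lam * exp3_design.matrix.flat_p + (1 - lam) * recon
            est = self._estimates_from(exp3_design, mix)
            corr = estimation_correlation(est, exp3_design.matrix)
            flags.append(corr["object_flag"].iloc[0])
        assert flags == [0.0, 1.0]

    def test_collinear_regressors_rejected(self, gen233):
        space = gen233.space
        rows = [
            dict(subject_id="s", experiment=0, session=1, estimation_block=1,
                 object=space.token(o), estimate_percent=50.0)
            for o in space.objects()
        ]
        with pytest.raises(ValueError):
            estimation_regression(pd.DataFrame(rows), gen233)


class TestPerformanceCurves:
    def test_omniscient_agent_always_better(self, exp3_design):
        rng = np.random.default_rng(0)
        from featlearn.tasks import sample_pair

        space = exp3_design.space
        p = exp3_design.matrix.flat_p
        rows = []
        for _ in range(300):
            a, b = sample_pair(exp3_design, rng)
            ia = np.ravel_multi_index(a, space.shape)
            ib = np.ravel_multi_index(b, space.shape)
            better = a if p[ia] >= p[ib] else b
            rows.append(
                dict(left_object=space.token(a), right_object=space.token(b),
                     choice="L" if better == a else "R",
                     chosen_object=space.token(better),
                     reward=int(rng.random() < p[max(ia, ib)]))
            )
        out = performance_curves(_toy_trials(rows), exp3_design)
        assert np.allclose(out["better"], 1.0)

    def test_random_agent_reward_matches_schedule_mean(self, exp1_design):
        from featlearn.models import MODEL_SPECS, ParamVector, simulate_agent

        spec = MODEL_SPECS["object_uncoupled"]
        params = ParamVector(alpha_rew=0.2, alpha_unr=0.2, sigma=1e9)
        log = simulate_agent(exp1_design, spec, params, seed=1)
        out = performance_curves(log, exp1_design)
        grand = log["reward"].mean()
        se = np.sqrt(0.25 / len(log))
        assert abs(grand - 0.5) < 4 * se


class TestTrendFit:
    def test_constant_series(self):
        out = trend_fit(np.full(6, 0.42))
        assert abs(out["b"]) < 1e-6

    def test_exact_exponential_recovered(self):
        t = np.arange(1, 9, dtype=float)
        y = 0.6 - 0.3 * np.exp(-t / 2.0)
        out = trend_fit(y, t)
        assert out["a"] == pytest.approx(0.6, abs=1e-6)
        assert out["b"] == pytest.approx(-0.3, abs=1e-6)
        assert out["tau"] == pytest.approx(2.0, abs=1e-5)

    def test_rising_series_asymptote(self):
        t = np.arange(1, 9, dtype=float)
        y = 0.7 - 0.4 * np.exp(-t / 3.0)
        out = trend_fit(y, t)
        assert out["a"] >= y[-1] - 0.05
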