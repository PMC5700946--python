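"""Descriptive and inferential analyses of choice and estimation data.

Covers the standard behavioral read-outs of the choice experiments:
learning/performance curves, the chance-level exclusion threshold, the
object- and feature-based differential responses to reward feedback
(win-stay/lose-stay logic and its feature-sharing analog), and the
regression/correlation analyses that quantify how much reported
reward-probability estimates reflect actual object probabilities versus
their feature-based reconstruction.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .environments import RewardMatrix, feature_profile
from .tasks import SessionDesign, drop_burn_in

__all__ = [
    "performance_curves",
    "exclusion_threshold",
    "differential_response",
    "estimation_regression",
    "estimation_correlation",
    "trend_fit",
]


def exclusion_threshold(n_trials: int) -> float:
    """Chance-performance exclusion threshold: 0.5 + 2 s.e.m.

    The s.e.m. is the binomial null standard error sqrt(0.25/N).  Reported
    rounded to 4 decimals (0.5406 for N=608, 0.5447 for N=500, 0.5404 for
    N=612).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return round(0.5 + 2.0 * np.sqrt(0.25 / n_trials), 4)


def _truth_lookup(design: SessionDesign):
    space = design.space

    def p_of(row, token):
        obj = space.parse_token(token)
        p = design.trial_p(int(row["session"]), int(row["trial"]))
        return p[np.ravel_multi_index(obj, space.shape)]

    return p_of


def performance_curves(
    trials: pd.DataFrame, design: SessionDesign, moving_window: Optional[int] = None
) -> pd.DataFrame:
    """Mean harvested reward and P(better option) by within-block position.

    For block designs the position is the within-block trial; for static
    designs it is the within-session trial, optionally smoothed with a
    moving average (the 20-trial moving box used for the static
    experiments).
    """
    p_of = _truth_lookup(design)
    df = trials.copy()
    p_left = df.apply(lambda r: p_of(r, r["left_object"]), axis=1)
    p_right = df.apply(lambda r: p_of(r, r["right_object"]), axis=1)
    p_cho = np.where(df["choice"] == "L", p_left, p_right)
    better = (
        (p_cho >= np.maximum(p_left, p_right) - 1e-12).astype(float)
    )
    # ties (equal probabilities) count as choosing the better option
    if design.L is not None:
        pos = (df["trial"] - 1) % design.L + 1
    else:
        pos = df["trial"]
    out = (
        pd.DataFrame(
            {"position": pos, "reward": df["reward"].astype(float), "better": better}
        )
        .groupby("position")
        .mean()
        .reset_index()
    )
    if moving_window:
        out["reward"] = (
            out["reward"].rolling(moving_window, min_periods=1, center=True).mean()
        )
        out["better"] = (
            out["better"].rolling(moving_window, min_periods=1, center=True).mean()
        )
    return out


def _shared_features(a: Tuple, b: Tuple) -> int:
    return sum(ai == bi for ai, bi in zip(a, b))


def _which_shared(a: Tuple, b: Tuple) -> Optional[int]:
    shared = [i for i, (ai, bi) in enumerate(zip(a, b)) if ai == bi]
    return shared[0] if len(shared) == 1 else None


def differential_response(
    trials: pd.DataFrame,
    design: SessionDesign,
    kind: str = "feature",
    feature_filter: str = "both",
) -> dict:
    """Differential response to the previous trial's reward feedback.

    ``kind='object'``: P(repeat the previously chosen object | it was
    rewarded) minus the same probability given it was unrewarded — the
    win-stay minus lose-stay contrast.

    ``kind='feature'``: over trials whose pair contains exactly one object
    sharing exactly one feature with the previously chosen object and one
    object sharing none, P(choose the sharing object | previous rewarded)
    minus P(... | previous unrewarded).  ``feature_filter`` restricts
    eligible trials to those where the shared feature is the design's
    informative feature ('more'), the other feature ('less'), or either
    ('both').

    Returns the differential, the two conditional probabilities, and the
    eligible-trial counts; NaN with count 0 when no trial qualifies.
    Consecutive-trial structure is respected within each subject and
    session.
    """
    if kind not in ("feature", "object"):
        raise ValueError("kind must be 'feature' or 'object'")
    space = design.space
    num = {1: [], 0: []}  # keyed by previous reward
    for (_, _), sub in trials.groupby(["subject_id", "session"], sort=False):
        prev_obj = None
        prev_r = None
        for row in sub.itertuples():
            left = space.parse_token(row.left_object)
            right = space.parse_token(row.right_object)
            cho = space.parse_token(row.chosen_object)
            if prev_obj is not None:
                if kind == "object":
                    if prev_obj in (left, right):
                        num[prev_r].append(1.0 if cho == prev_obj else 0.0)
                else:
                    sl = _shared_features(prev_obj, left)
                    sr = _shared_features(prev_obj, right)
                    # exclude pairs containing the previous object itself
                    if {sl, sr} == {1, 0} and prev_obj not in (left, right):
                        sharer = left if sl == 1 else right
                        which = _which_shared(prev_obj, sharer)
                        ok = (
                            feature_filter == "both"
                            or (
                                feature_filter == "more"
                                and which == design.informative_feature
                            )
                            or (
                                feature_filter == "less"
                                and which != design.informative_feature
                            )
                        )
                        if ok:
                            num[prev_r].append(1.0 if cho == sharer else 0.0)
            prev_obj = cho
            prev_r = int(row.reward)
    p_rew = float(np.mean(num[1])) if num[1] else np.nan
    p_unr = float(np.mean(num[0])) if num[0] else np.nan
    return {
        "differential": p_rew - p_unr if num[1] and num[0] else np.nan,
        "p_given_rewarded": p_rew,
        "p_given_unrewarded": p_unr,
        "n_rewarded": len(num[1]),
        "n_unrewarded": len(num[0]),
    }


def _regressors(matrix: RewardMatrix, tokens: Sequence[str]):
    space = matrix.space
    est = feature_profile(matrix).estimated.ravel()
    p = matrix.flat_p
    idx = [
        np.ravel_multi_index(space.parse_token(t), space.shape) for t in tokens
    ]
    return p[idx], est[idx]


def estimation_regression(
    estimates: pd.DataFrame,
    matrix: RewardMatrix,
    by_block: bool = True,
) -> pd.DataFrame:
    """OLS of reported estimates on actual and feature-reconstructed p.

    Estimates (percent) are regressed on the object's actual reward
    probability, its feature-based reconstruction, and a constant; the
    relative weight ``beta_obj / (beta_obj + beta_feat)`` tracks the shift
    from feature-based (0) to object-based (1) valuation.  Pooled across
    subjects per estimation block by default.  A fully generalizable matrix
    makes the two regressors collinear and is rejected.
    """
    p, est = _regressors(matrix, estimates["object"])
    # fully generalizable matrices give correlations >= 0.999 between the
    # two regressors; the design matrix is then numerically degenerate
    if np.ptp(p) == 0 or abs(np.corrcoef(p, est)[0, 1]) > 0.999:
        raise ValueError(
            "actual and feature-reconstructed probabilities are collinear "
            "(fully generalizable matrix): the regression is degenerate"
        )
    df = estimates.copy()
    df["_p"] = p
    df["_est"] = est
    df["_y"] = df["estimate_percent"].astype(float) / 100.0
    groups = df.groupby("estimation_block") if by_block else [(0, df)]
    rows = []
    for block, sub in groups:
        X = np.column_stack([sub["_p"], sub["_est"], np.ones(len(sub))])
        beta, res, rank, _ = np.linalg.lstsq(X, sub["_y"], rcond=None)
        yhat = X @ beta
        ss_res = float(np.sum((sub["_y"] - yhat) ** 2))
        ss_tot = float(np.sum((sub["_y"] - sub["_y"].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        denom = beta[0] + beta[1]
        rows.append(
            {
                "estimation_block": block,
                "beta_object": beta[0],
                "beta_feature": beta[1],
                "bias": beta[2],
                "r_squared": r2,
                "relative_weight": beta[0] / denom if denom != 0 else np.nan,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def estimation_correlation(
    estimates: pd.DataFrame, matrix: RewardMatrix
) -> pd.DataFrame:
    """Per subject and block: is the estimate closer to actual or feature p?

    The flag is ``corr(estimates, p) > corr(estimates, p_feature)``; the
    fraction of flagged subjects per estimation block summarizes the
    population shift toward object-based valuation.  Zero-variance
    estimates yield an NA flag.
    """
    rows = []
    for (block, subject), sub in estimates.groupby(
        ["estimation_block", "subject_id"]
    ):
        p, est = _regressors(matrix, sub["object"])
        y = sub["estimate_percent"].astype(float).to_numpy() / 100.0
        if len(sub) < 3 or np.ptp(y) == 0.0:
            flag = np.nan
        else:
            flag = float(
                stats.pearsonr(y, p).statistic
                > stats.pearsonr(y, est).statistic
            )
        rows.append(
            {"estimation_block": block, "subject_id": subject, "object_flag": flag}
        )
    out = pd.DataFrame(rows)
    frac = (
        out.groupby("estimation_block")["object_flag"]
        .mean()
        .rename("fraction_object")
        .reset_index()
    )
    return out.merge(frac, on="estimation_block")


def trend_fit(series: np.ndarray, t: Optional[np.ndarray] = None) -> dict:
    """Least-squares fit of ``y = a + b * exp(-t / tau)`` to a block series."""
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points for the exponential trend")
    t = np.arange(1.0, y.size + 1) if t is None else np.asarray(t, float)

    def model(t, a, b, tau):
        return a + b * np.exp(-t / tau)

    best = None
    for tau0 in (1.0, 2.0, 5.0):
        try:
            popt, _ = optimize.curve_fit(
                model,
                t,
                y,
                p0=[y[-1], y[0] - y[-1], tau0],
                maxfev=5000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or resid < best["residual"]:
            best = {
                "a": float(popt[0]),
                "b": float(popt[1]),
                "tau": float(popt[2]),
                "residual": resid,
            }
    if best is None:
        return {"a": np.nan, "b": np.nan, "tau": np.nan, "residual": np.nan,
                "converged": False}
    best["converged"] = True
    return best
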