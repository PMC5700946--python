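"""Idealized object-based and feature-based learners.

Two learners observe the same bandit-style task over a factorial reward
environment.  The object-based learner tracks one value per object; the
feature-based learner tracks one value per feature instance and reconstructs
object values with the Bayes-rule odds combination.  The differential signal
measures how well a learner's current values order objects by their true
reward probability; the cross-over point is the number of initial trials for
which the feature-based learner carries the stronger signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .environments import RewardMatrix, bayes_combine

__all__ = [
    "ValueState",
    "LearnerTrace",
    "object_learner_update",
    "feature_learner_update",
    "estimate_object_values_from_features",
    "differential_signal",
    "simulate_framework",
    "crossover_point",
]

_CLAMP = 1e-6


@dataclass
class ValueState:
    """Current value estimates of both learners over one feature space."""

    space: "FeatureSpace"
    V_object: np.ndarray = None  # flat, length n**m
    V_feature: np.ndarray = None  # (m, n)
    t: int = 0

    def __post_init__(self):
        if self.V_object is None:
            self.V_object = np.full(self.space.n_objects, 0.5)
        if self.V_feature is None:
            self.V_feature = np.full((self.space.m, self.space.n), 0.5)

    def object_index(self, obj) -> int:
        idx = np.ravel_multi_index(tuple(obj), self.space.shape)
        return int(idx)


@dataclass
class LearnerTrace:
    """Run-averaged differential-signal trajectories of the two learners."""

    S_O: np.ndarray
    S_F: np.ndarray

    @property
    def crossover(self) -> float:
        return crossover_point(self)


def object_learner_update(
    state: ValueState, chosen_object, r: int, alpha: float
) -> ValueState:
    """Move the chosen object's value toward the outcome by fraction alpha."""
    idx = state.object_index(chosen_object)
    v = state.V_object[idx]
    state.V_object[idx] = v + alpha * (r - v)
    state.t += 1
    return state


def feature_learner_update(
    state: ValueState, chosen_object, r: int, alpha: float
) -> ValueState:
    """Update every feature instance of the chosen object toward the outcome."""
    obj = tuple(chosen_object)
    if len(obj) != state.space.m:
        raise ValueError(f"object {obj} does not match m={state.space.m}")
    for i, j in enumerate(obj):
        v = state.V_feature[i, j]
        state.V_feature[i, j] = v + alpha * (r - v)
    state.t += 1
    return state


def estimate_object_values_from_features(state: ValueState) -> np.ndarray:
    """Bayes-combine current feature values into per-object estimates.

    Feature values are clamped to [1e-6, 1 - 1e-6] first so that the odds
    combination stays defined when a value saturates.
    """
    vf = np.clip(state.V_feature, _CLAMP, 1.0 - _CLAMP)
    space = state.space
    num = np.ones(space.shape)
    comp = np.ones(space.shape)
    for i in range(space.m):
        shape = [1] * space.m
        shape[i] = space.n
        num = num * vf[i].reshape(shape)
        comp = comp * (1.0 - vf[i]).reshape(shape)
    return (num / (num + comp)).ravel()


def _sign_weights(p_flat: np.ndarray) -> np.ndarray:
    """c_a = sum_b sign(p_a - p_b); lets the pair double-sum collapse to 2*c.V."""
    return np.sign(p_flat[:, None] - p_flat[None, :]).sum(axis=1)


def differential_signal(values: np.ndarray, matrix: RewardMatrix) -> float:
    """Pairwise-normalized measure of how well ``values`` order the objects.

    Computes ``(1/(D(D-1))) * sum_{a,b} (V_a - V_b) * sign(p_a - p_b)`` with
    ``sign(0) = 0``; the double sum collapses to ``2 * sum_a c_a V_a`` with
    ``c_a = sum_b sign(p_a - p_b)``.
    """
    p = matrix.flat_p
    values = np.asarray(values, dtype=float).ravel()
    if values.shape != p.shape:
        raise ValueError("values are not aligned with the matrix objects")
    D = p.size
    return float(2.0 * _sign_weights(p) @ values / (D * (D - 1)))


def simulate_framework(
    matrix: RewardMatrix,
    alpha: float,
    n_trials: int,
    n_runs: int,
    seed: int,
    sigma: float = 0.1,
    policy: str = "logistic",
) -> LearnerTrace:
    """Simulate both learners and return run-averaged differential signals.

    On each trial a pair of distinct objects is drawn uniformly; each learner
    chooses via a logistic on its own estimated values (``policy="logistic"``,
    stochasticity ``sigma``) or uniformly (``policy="random"``), and receives
    a Bernoulli outcome from the chosen object's true probability.  Both
    learners share the same random draws, so for m = 1 (where the two models
    coincide) their trajectories are identical.
    """
    space = matrix.space
    D = space.n_objects
    p = matrix.flat_p
    c = _sign_weights(p)
    norm = D * (D - 1)
    # feature indices of each flat object id, shape (D, m)
    feat_idx = np.array(list(np.ndindex(space.shape)), dtype=np.intp)

    rng = np.random.default_rng(seed)
    R = n_runs
    V_obj = np.full((R, D), 0.5)
    V_feat = np.full((R, space.m, space.n), 0.5)
    runs = np.arange(R)

    S_O = np.empty(n_trials)
    S_F = np.empty(n_trials)

    def feature_estimates() -> np.ndarray:
        vf = np.clip(V_feat, _CLAMP, 1.0 - _CLAMP)
        num = np.ones((R, D))
        comp = np.ones((R, D))
        for i in range(space.m):
            col = vf[:, i, :][:, feat_idx[:, i]]
            num *= col
            comp *= 1.0 - col
        return num / (num + comp)

    for t in range(n_trials):
        a = rng.integers(0, D, size=R)
        b = (a + 1 + rng.integers(0, D - 1, size=R)) % D
        u_choice = rng.random(R)
        u_reward = rng.random(R)

        est_f = feature_estimates()
        if policy == "logistic":
            p_left_o = 1.0 / (1.0 + np.exp(-(V_obj[runs, a] - V_obj[runs, b]) / sigma))
            p_left_f = 1.0 / (
                1.0 + np.exp(-(est_f[runs, a] - est_f[runs, b]) / sigma)
            )
        elif policy == "random":
            p_left_o = p_left_f = np.full(R, 0.5)
        else:
            raise ValueError(f"unknown policy {policy!r}")

        cho_o = np.where(u_choice < p_left_o, a, b)
        cho_f = np.where(u_choice < p_left_f, a, b)
        r_o = (u_reward < p[cho_o]).astype(float)
        r_f = (u_reward < p[cho_f]).astype(float)

        V_obj[runs, cho_o] += alpha * (r_o - V_obj[runs, cho_o])
        for i in range(space.m):
            jj = feat_idx[cho_f, i]
            V_feat[runs, i, jj] += alpha * (r_f - V_feat[runs, i, jj])

        S_O[t] = np.mean(2.0 * (V_obj @ c) / norm)
        S_F[t] = np.mean(2.0 * (feature_estimates() @ c) / norm)

    return LearnerTrace(S_O=S_O, S_F=S_F)


def crossover_point(trace: LearnerTrace) -> float:
    """Number of initial trials on which the feature-based signal dominates.

    Returns the first 0-based trial index at which the run-averaged object
    signal exceeds the feature signal: 0 means object-based learning is
    superior from the onset; ``inf`` means the feature-based learner dominates
    for the whole simulated horizon.
    """
    above = np.asarray(trace.S_O) > np.asarray(trace.S_F)
    hits = np.flatnonzero(above)
    if hits.size == 0:
        return float("inf")
    return float(hits[0])
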