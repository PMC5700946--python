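"""Trial-by-trial reinforcement-learning models of choice behavior.

Seven models are defined by a representation (object vs. feature), a coupling
flag (whether the unchosen option is updated in the opposite direction), an
optional decay of unused values toward 0.5, and an optional attentional
variant of the feature model with decay (separate learning rates and weights
per feature).  All models share the update skeleton

    V <- V + alpha_rew * (1 - V)   after a rewarded choice
    V <- V - alpha_unr * V         after an unrewarded choice

and a logistic choice rule on the (weighted) value difference between the
two presented options plus a left-side bias.  Likelihood evaluation and agent
simulation replay the same update rules; the inner loops are compiled with
numba for the fitting and recovery workloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .environments import FeatureSpace
from .tasks import SessionDesign, generate_trial_stream

__all__ = [
    "ModelSpec",
    "ParamVector",
    "MODEL_SPECS",
    "update_uncoupled",
    "update_coupled",
    "apply_decay",
    "choice_prob_object",
    "choice_prob_feature",
    "negative_log_likelihood",
    "simulate_agent",
    "encode_trials",
    "TRIAL_LOG_COLUMNS",
]

_P_FLOOR = 1e-10

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "experiment",
    "session",
    "trial",
    "block",
    "schedule_id",
    "left_object",
    "right_object",
    "choice",
    "chosen_object",
    "reward",
    "reward_left",
    "reward_right",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structural flags identifying one RL model."""

    representation: str = "object"  # 'object' | 'feature'
    coupling: str = "uncoupled"  # 'uncoupled' | 'coupled'
    decay: bool = False
    attentional: bool = False
    full_feedback: bool = False  # experiment-driven: update both options
    update_shared: bool = False  # rejected variant: update shared features too
    reset_sessions: bool = False  # reset values at session boundaries

    def __post_init__(self):
        if self.representation not in ("object", "feature"):
            raise ValueError(f"bad representation {self.representation!r}")
        if self.coupling not in ("uncoupled", "coupled"):
            raise ValueError(f"bad coupling {self.coupling!r}")
        if self.coupling == "coupled" and self.decay:
            raise ValueError("decay applies only to the uncoupled models")
        if self.attentional and not (
            self.representation == "feature" and self.decay
        ):
            raise ValueError(
                "the attentional variant extends the feature model with decay"
            )

    @property
    def name(self) -> str:
        if self.attentional:
            return "feature_decay_attn"
        base = self.representation
        if self.decay:
            return f"{base}_decay"
        return f"{base}_{self.coupling}"

    def n_params(self, m: int = 2, n_sessions: int = 1) -> int:
        """Free-parameter count (normative for this package).

        object uncoupled/coupled: alpha_rew, alpha_unr, sigma, bias -> 4;
        +1 for decay.  feature uncoupled/coupled: alpha_rew, alpha_unr,
        m weights, bias -> m+3; +1 for decay.  attentional: m learning
        rates, d, m weights per session, bias.
        """
        if self.representation == "object":
            return 4 + (1 if self.decay else 0)
        if self.attentional:
            return m + 1 + m * n_sessions + 1
        return 3 + m + (1 if self.decay else 0)


#: the six fit-side models of the recovery analyses, by name
MODEL_SPECS = {
    s.name: s
    for s in [
        ModelSpec("object", "uncoupled"),
        ModelSpec("object", "coupled"),
        ModelSpec("object", "uncoupled", decay=True),
        ModelSpec("feature", "uncoupled"),
        ModelSpec("feature", "coupled"),
        ModelSpec("feature", "uncoupled", decay=True),
        ModelSpec("feature", "uncoupled", decay=True, attentional=True),
    ]
}


@dataclass
class ParamVector:
    """Parameters of one RL model.

    ``w`` holds feature weights with shape ``(n_sessions, m)``; for models
    without per-session weights a single row is broadcast.  ``alpha_feature``
    (length m) replaces ``alpha_rew``/``alpha_unr`` in the attentional model.
    """

    alpha_rew: float = 0.2
    alpha_unr: float = 0.2
    d: float = 0.02
    sigma: float = 0.1
    bias: float = 0.0
    w: Optional[np.ndarray] = None
    alpha_feature: Optional[np.ndarray] = None

    def weights(self, m: int, n_sessions: int) -> np.ndarray:
        if self.w is None:
            w = np.full((n_sessions, m), 5.0)
        else:
            w = np.atleast_2d(np.asarray(self.w, dtype=float))
            if w.shape[0] == 1 and n_sessions > 1:
                w = np.repeat(w, n_sessions, axis=0)
        if w.shape != (n_sessions, m):
            raise ValueError(f"weights shape {w.shape} != {(n_sessions, m)}")
        return w

    def learning_rates(self, spec: ModelSpec, m: int):
        if spec.attentional:
            if self.alpha_feature is None:
                raise ValueError("attentional model needs alpha_feature")
            a = np.asarray(self.alpha_feature, dtype=float)
            return a.copy(), a.copy()
        return (
            np.full(m, float(self.alpha_rew)),
            np.full(m, float(self.alpha_unr)),
        )


# ---------------------------------------------------------------------------
# Elementary update and choice rules (reference scalar forms)
# ---------------------------------------------------------------------------


def update_uncoupled(v: float, r: int, alpha_rew: float, alpha_unr: float) -> float:
    """Chosen-value update with separate rewarded/unrewarded learning rates."""
    if r == 1:
        return v + alpha_rew * (1.0 - v)
    return v - alpha_unr * v


def update_coupled(v_unchosen: float, r: int, alpha_rew: float, alpha_unr: float) -> float:
    """Unchosen-value update in the opposite direction (anti-correlated rewards)."""
    if r == 1:
        return v_unchosen - alpha_rew * v_unchosen
    return v_unchosen + alpha_unr * (1.0 - v_unchosen)


def apply_decay(v, d: float):
    """Relax values toward the neutral 0.5 with rate d."""
    v = np.asarray(v, dtype=float)
    return v - d * (v - 0.5)


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def choice_prob_object(v_left: float, v_right: float, sigma: float, bias: float = 0.0) -> float:
    """P(choose left) for the object models: logistic of scaled value difference."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _logistic((v_left - v_right) / sigma + bias)


def choice_prob_feature(
    v_left: np.ndarray, v_right: np.ndarray, w: np.ndarray, bias: float = 0.0
) -> float:
    """P(choose left) for the feature models: weighted feature-value contrast."""
    v_left = np.asarray(v_left, float)
    v_right = np.asarray(v_right, float)
    w = np.asarray(w, float)
    return _logistic(float(np.dot(w, v_left - v_right)) + bias)


# ---------------------------------------------------------------------------
# Compiled replay / simulation kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _step(
    rep,
    coupled,
    decay_on,
    full_fb,
    update_shared,
    V_obj,
    V_feat,
    lo,
    ro,
    lf,
    rf,
    cho_is_left,
    r_cho,
    r_unc,
    a_rew,
    a_unr,
    d,
    m,
):
    """Apply one trial's value updates in place."""
    if cho_is_left:
        co, uo = lo, ro
        cf, uf = lf, rf
    else:
        co, uo = ro, lo
        cf, uf = rf, lf
    if rep == 0:
        old_c = V_obj[co]
        old_u = V_obj[uo]
        if r_cho == 1:
            V_obj[co] = old_c + a_rew[0] * (1.0 - old_c)
        else:
            V_obj[co] = old_c - a_unr[0] * old_c
        touched_u = False
        if coupled == 1:
            if r_cho == 1:
                V_obj[uo] = old_u - a_rew[0] * old_u
            else:
                V_obj[uo] = old_u + a_unr[0] * (1.0 - old_u)
            touched_u = True
        elif full_fb == 1:
            if r_unc == 1:
                V_obj[uo] = old_u + a_rew[0] * (1.0 - old_u)
            else:
                V_obj[uo] = old_u - a_unr[0] * old_u
            touched_u = True
        if decay_on == 1:
            for k in range(V_obj.shape[0]):
                if k != co and not (touched_u and k == uo):
                    V_obj[k] -= d * (V_obj[k] - 0.5)
    else:
        for i in range(m):
            shared = cf[i] == uf[i]
            upd_c = (not shared) or update_shared == 1
            upd_u = False
            if upd_c:
                old = V_feat[i, cf[i]]
                if r_cho == 1:
                    V_feat[i, cf[i]] = old + a_rew[i] * (1.0 - old)
                else:
                    V_feat[i, cf[i]] = old - a_unr[i] * old
            if not shared:
                if coupled == 1:
                    old = V_feat[i, uf[i]]
                    if r_cho == 1:
                        V_feat[i, uf[i]] = old - a_rew[i] * old
                    else:
                        V_feat[i, uf[i]] = old + a_unr[i] * (1.0 - old)
                    upd_u = True
                elif full_fb == 1:
                    old = V_feat[i, uf[i]]
                    if r_unc == 1:
                        V_feat[i, uf[i]] = old + a_rew[i] * (1.0 - old)
                    else:
                        V_feat[i, uf[i]] = old - a_unr[i] * old
                    upd_u = True
            if decay_on == 1:
                for j in range(V_feat.shape[1]):
                    if j == cf[i] and upd_c:
                        continue
                    if upd_u and j == uf[i]:
                        continue
                    V_feat[i, j] -= d * (V_feat[i, j] - 0.5)


@njit(cache=True)
def _p_left(rep, V_obj, V_feat, lo, ro, lf, rf, sigma, bias, w_sess, m):
    if rep == 0:
        z = (V_obj[lo] - V_obj[ro]) / sigma + bias
    else:
        z = bias
        for i in range(m):
            z += w_sess[i] * (V_feat[i, lf[i]] - V_feat[i, rf[i]])
    if z > 35.0:
        return 1.0 - 1e-15
    if z < -35.0:
        return 1e-15
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _replay_nll(
    rep,
    coupled,
    decay_on,
    full_fb,
    update_shared,
    left_obj,
    right_obj,
    left_f,
    right_f,
    choice,
    r_left,
    r_right,
    new_sess,
    sess_idx,
    n_objects,
    m,
    n,
    a_rew,
    a_unr,
    d,
    sigma,
    bias,
    w,
    out_p,
):
    T = left_obj.shape[0]
    V_obj = np.full(n_objects, 0.5)
    V_feat = np.full((m, n), 0.5)
    nll = 0.0
    for t in range(T):
        if new_sess[t]:
            V_obj[:] = 0.5
            V_feat[:] = 0.5
        p_left = _p_left(
            rep,
            V_obj,
            V_feat,
            left_obj[t],
            right_obj[t],
            left_f[t],
            right_f[t],
            sigma,
            bias,
            w[sess_idx[t]],
            m,
        )
        p_obs = p_left if choice[t] == 0 else 1.0 - p_left
        if p_obs < _P_FLOOR:
            p_obs = _P_FLOOR
        out_p[t] = p_obs
        nll -= np.log(p_obs)
        cho_is_left = choice[t] == 0
        r_cho = r_left[t] if cho_is_left else r_right[t]
        r_unc = r_right[t] if cho_is_left else r_left[t]
        _step(
            rep,
            coupled,
            decay_on,
            full_fb,
            update_shared,
            V_obj,
            V_feat,
            left_obj[t],
            right_obj[t],
            left_f[t],
            right_f[t],
            cho_is_left,
            r_cho,
            r_unc,
            a_rew,
            a_unr,
            d,
            m,
        )
    return nll


@njit(cache=True)
def _simulate_choices(
    rep,
    coupled,
    decay_on,
    full_fb,
    update_shared,
    left_obj,
    right_obj,
    left_f,
    right_f,
    r_left,
    r_right,
    new_sess,
    sess_idx,
    u_choice,
    n_objects,
    m,
    n,
    a_rew,
    a_unr,
    d,
    sigma,
    bias,
    w,
    out_choice,
):
    T = left_obj.shape[0]
    V_obj = np.full(n_objects, 0.5)
    V_feat = np.full((m, n), 0.5)
    for t in range(T):
        if new_sess[t]:
            V_obj[:] = 0.5
            V_feat[:] = 0.5
        p_left = _p_left(
            rep,
            V_obj,
            V_feat,
            left_obj[t],
            right_obj[t],
            left_f[t],
            right_f[t],
            sigma,
            bias,
            w[sess_idx[t]],
            m,
        )
        cho_is_left = u_choice[t] < p_left
        out_choice[t] = 0 if cho_is_left else 1
        r_cho = r_left[t] if cho_is_left else r_right[t]
        r_unc = r_right[t] if cho_is_left else r_left[t]
        _step(
            rep,
            coupled,
            decay_on,
            full_fb,
            update_shared,
            V_obj,
            V_feat,
            left_obj[t],
            right_obj[t],
            left_f[t],
            right_f[t],
            cho_is_left,
            r_cho,
            r_unc,
            a_rew,
            a_unr,
            d,
            m,
        )


# ---------------------------------------------------------------------------
# Encoding and public entry points
# ---------------------------------------------------------------------------


@dataclass
class EncodedTrials:
    """Trial log flattened to contiguous arrays for the compiled kernels."""

    space: FeatureSpace
    left_obj: np.ndarray
    right_obj: np.ndarray
    left_f: np.ndarray
    right_f: np.ndarray
    choice: np.ndarray
    r_left: np.ndarray
    r_right: np.ndarray
    new_sess: np.ndarray
    sess_idx: np.ndarray
    n_sessions: int

    @property
    def n_trials(self) -> int:
        return self.left_obj.shape[0]


def encode_trials(
    trials: pd.DataFrame, space: FeatureSpace, reset_sessions: bool = False
) -> EncodedTrials:
    """Flatten a trial-log DataFrame into kernel-ready arrays.

    ``reset_sessions`` marks session starts so that values are re-initialized
    there (new stimulus sets in Experiments 3/4); otherwise values carry over.
    """
    tok = [space.parse_token(t) for t in trials["left_object"]]
    left_f = np.asarray(tok, dtype=np.int64)
    tok = [space.parse_token(t) for t in trials["right_object"]]
    right_f = np.asarray(tok, dtype=np.int64)
    left_obj = np.ravel_multi_index(left_f.T, space.shape).astype(np.int64)
    right_obj = np.ravel_multi_index(right_f.T, space.shape).astype(np.int64)
    choice = np.where(np.asarray(trials["choice"]) == "L", 0, 1).astype(np.int64)
    sess = np.asarray(trials["session"], dtype=np.int64)
    new_sess = np.zeros(len(trials), dtype=np.bool_)
    if reset_sessions and len(trials):
        new_sess[0] = True
        new_sess[1:] = sess[1:] != sess[:-1]
    r_cho = np.asarray(trials["reward"], dtype=np.int64)
    if "reward_left" in trials and trials["reward_left"].notna().all():
        r_left = np.asarray(trials["reward_left"], dtype=np.int64)
        r_right = np.asarray(trials["reward_right"], dtype=np.int64)
    else:
        # only the chosen outcome is observed; the unchosen slot is unused
        r_left = np.where(choice == 0, r_cho, 0).astype(np.int64)
        r_right = np.where(choice == 1, r_cho, 0).astype(np.int64)
    sess_u = np.unique(sess)
    sess_idx = np.searchsorted(sess_u, sess).astype(np.int64)
    return EncodedTrials(
        space=space,
        left_obj=left_obj,
        right_obj=right_obj,
        left_f=left_f,
        right_f=right_f,
        choice=choice,
        r_left=r_left,
        r_right=r_right,
        new_sess=new_sess,
        sess_idx=sess_idx,
        n_sessions=len(sess_u),
    )


def _kernel_args(spec: ModelSpec, params: ParamVector, enc: EncodedTrials):
    m, n = enc.space.m, enc.space.n
    a_rew, a_unr = params.learning_rates(spec, m)
    w = params.weights(m, enc.n_sessions)
    return (
        0 if spec.representation == "object" else 1,
        1 if spec.coupling == "coupled" else 0,
        1 if spec.decay else 0,
        1 if spec.full_feedback else 0,
        1 if spec.update_shared else 0,
        enc.left_obj,
        enc.right_obj,
        enc.left_f,
        enc.right_f,
    ), (
        enc.new_sess,
        enc.sess_idx,
        enc.space.n_objects,
        m,
        n,
        a_rew,
        a_unr,
        float(params.d if spec.decay else 0.0),
        float(params.sigma),
        float(params.bias),
        w,
    )


def negative_log_likelihood(
    trials: pd.DataFrame | EncodedTrials,
    spec: ModelSpec,
    params: ParamVector,
    space: Optional[FeatureSpace] = None,
    per_trial: bool = False,
):
    """Total -LL of a trial log under one model, replaying its update rules.

    Values start at 0.5, are reset at session boundaries when the spec says
    so, and the observed-choice probability is floored at 1e-10.  With
    ``per_trial=True`` returns ``(nll, p_choice array)``.
    """
    if isinstance(trials, EncodedTrials):
        enc = trials
    else:
        if space is None:
            raise ValueError("space is required when passing a DataFrame")
        enc = encode_trials(trials, space, reset_sessions=spec.reset_sessions)
    head, tail = _kernel_args(spec, params, enc)
    out_p = np.empty(enc.n_trials)
    nll = _replay_nll(*head, enc.choice, enc.r_left, enc.r_right, *tail, out_p)
    if per_trial:
        return float(nll), -np.log(out_p)
    return float(nll)


def simulate_agent(
    design: SessionDesign,
    spec: ModelSpec,
    params: ParamVector,
    seed: int,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Play the task, sampling choices from the model's own probabilities.

    Returns a standard trial log with pregenerated independent outcomes for
    both presented objects; the ``reward`` column is the chosen side's
    outcome (both sides are reported when the design gives full feedback).
    """
    stream = generate_trial_stream(design, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    T = design.total_trials
    space = design.space
    left_f = np.array(
        np.unravel_index(stream["left"], space.shape), dtype=np.int64
    ).T.copy()
    right_f = np.array(
        np.unravel_index(stream["right"], space.shape), dtype=np.int64
    ).T.copy()
    sess = stream["session"].astype(np.int64)
    new_sess = np.zeros(T, dtype=np.bool_)
    if spec.reset_sessions:
        new_sess[0] = True
        new_sess[1:] = sess[1:] != sess[:-1]
    sess_idx = (sess - 1).astype(np.int64)
    n_sessions = design.sessions
    m, n = space.m, space.n
    a_rew, a_unr = params.learning_rates(spec, m)
    w = params.weights(m, n_sessions)
    out_choice = np.empty(T, dtype=np.int64)
    _simulate_choices(
        0 if spec.representation == "object" else 1,
        1 if spec.coupling == "coupled" else 0,
        1 if spec.decay else 0,
        1 if spec.full_feedback else 0,
        1 if spec.update_shared else 0,
        stream["left"].astype(np.int64),
        stream["right"].astype(np.int64),
        left_f,
        right_f,
        stream["r_left"].astype(np.int64),
        stream["r_right"].astype(np.int64),
        new_sess,
        sess_idx,
        rng.random(T),
        space.n_objects,
        m,
        n,
        a_rew,
        a_unr,
        float(params.d if spec.decay else 0.0),
        float(params.sigma),
        float(params.bias),
        w,
        out_choice,
    )
    chosen = np.where(out_choice == 0, stream["left"], stream["right"])
    reward = np.where(out_choice == 0, stream["r_left"], stream["r_right"])
    tokens = [space.token(o) for o in space.objects()]
    tok = np.array(tokens)
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "experiment": design.experiment,
            "session": sess,
            "trial": stream["trial"],
            "block": stream["block"],
            "schedule_id": stream["schedule_id"],
            "left_object": tok[stream["left"]],
            "right_object": tok[stream["right"]],
            "choice": np.where(out_choice == 0, "L", "R"),
            "chosen_object": tok[chosen],
            "reward": reward.astype(int),
            "reward_left": (
                stream["r_left"].astype(int) if design.full_feedback else pd.NA
            ),
            "reward_right": (
                stream["r_right"].astype(int) if design.full_feedback else pd.NA
            ),
        },
        columns=TRIAL_LOG_COLUMNS,
    )
    return df
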