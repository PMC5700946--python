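"""Parallel and hierarchical decision-making-and-learning network models.

Both networks carry two sets of value-encoding neurons — object-value
encoding (OVE) and feature-value encoding (FVE) — whose input synapses are
binary and plastic.  At the mean-field level each pool's synaptic strength F
(the fraction of synapses in the strong state) is updated after feedback:
potentiation ``F += q+ (1-F)`` on reward, depression ``F -= q- F`` on
non-reward for pools selective to the chosen object/features, and decay
``F -= q_d (F - 0.5)`` for all other pools.  Connection strengths C_O, C_F
from the two sets gate their influence on choice and are trained by the same
stochastic rule.

The PDML model combines both sets in one final decision and reinforces the
connections of whichever set's stand-alone decision agreed with the final
choice.  The HDML model first selects the set with the stronger signal,
decides using that set alone, and trains only the selected set's connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .environments import RewardMatrix
from .framework import _sign_weights
from .models import TRIAL_LOG_COLUMNS
from .tasks import SessionDesign, _pair_pool

__all__ = [
    "NetworkParams",
    "NetworkTrace",
    "value_synapse_update",
    "connection_update",
    "pdml_choice_prob",
    "hdml_select_prob",
    "simulate_network",
    "sweep_environments",
    "binary_synapse_trajectory",
    "mean_field_trajectory",
]


@dataclass
class NetworkParams:
    """Plasticity and choice parameters shared by the two network models.

    Defaults are the simulation values used throughout: value-synapse rates
    0.15, connection rates 0.075, decay 0.015 (0.03 for the larger 4x4
    environment), choice stochasticity 0.1.
    """

    q_plus_V: float = 0.15
    q_minus_V: float = 0.15
    q_plus_C: float = 0.075
    q_minus_C: float = 0.075
    q_d: float = 0.015
    sigma: float = 0.1
    #: if True the whole logit is divided by sigma; if False only the
    #: feature-term average is (the literal reading of the printed choice rule)
    scale_whole_logit: bool = False

    def __post_init__(self):
        for name in ("q_plus_V", "q_minus_V", "q_plus_C", "q_minus_C", "q_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class NetworkTrace:
    """Run-averaged per-trial trajectories of one network simulation."""

    C_O: np.ndarray
    C_F: np.ndarray
    S_O: np.ndarray
    S_F: np.ndarray
    p_select_OVE: np.ndarray  # HDML only; 0.5 placeholder for PDML
    reward: np.ndarray

    @property
    def W_O(self) -> np.ndarray:
        return self.C_O * self.S_O

    @property
    def W_F(self) -> np.ndarray:
        return self.C_F * self.S_F

    @property
    def performance(self) -> float:
        return float(self.reward.mean())


def value_synapse_update(F: float, r: int, q_plus: float, q_minus: float) -> float:
    """Mean-field strength update of a pool selective to the chosen option."""
    if r == 1:
        return F + q_plus * (1.0 - F)
    return F - q_minus * F


def connection_update(C: float, r: int, q_plus: float, q_minus: float) -> float:
    return value_synapse_update(C, r, q_plus, q_minus)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def pdml_choice_prob(
    dF_obj: float,
    dF_feat_sum: float,
    C_O: float,
    C_F: float,
    m: int,
    params: NetworkParams,
) -> float:
    """P(choose option 1) of the PDML final decision circuit."""
    feat = C_F * dF_feat_sum / m
    if params.scale_whole_logit:
        z = (C_O * dF_obj + feat) / params.sigma
    else:
        z = C_O * dF_obj + feat / params.sigma
    return float(_logistic(z))


def hdml_select_prob(
    dF_obj: float,
    dF_feat_sum: float,
    C_O: float,
    C_F: float,
    m: int,
    params: NetworkParams,
) -> float:
    """P(select the OVE signal) in the HDML signal-selection circuit.

    Signal strength is the magnitude of the weighted value difference of the
    two options in each set; the selection logit is the strength difference.
    """
    so = C_O * abs(dF_obj)
    sf = C_F * abs(dF_feat_sum) / m
    if params.scale_whole_logit:
        z = (so - sf) / params.sigma
    else:
        z = so - sf / params.sigma
    return float(_logistic(z))


@njit(cache=True)
def _sim_network(
    model,  # 0 = PDML, 1 = HDML
    scale_whole,
    full_fb,  # update both presented objects' pools, each with its outcome
    left_obj,  # (R, T)
    right_obj,
    r_left,
    r_right,
    u_choice,
    u_aux_o,
    u_aux_f,
    u_select,
    feat_idx,  # (D, m)
    c_weights,  # (n_sched, D) pairwise sign weights of the current truth
    sched_of,  # (T,)
    m,
    n,
    D,
    qpv,
    qmv,
    qpc,
    qmc,
    qd,
    sigma,
    trace_sums,  # (T, 6): C_O, C_F, S_O, S_F, p_OVE, reward
    out_choice,  # (R, T) int8: 0 left, 1 right
):
    R, T = left_obj.shape
    norm = D * (D - 1)
    for run in range(R):
        F_obj = np.full(D, 0.5)
        F_feat = np.full((m, n), 0.5)
        C_O = 0.5
        C_F = 0.5
        for t in range(T):
            lo = left_obj[run, t]
            ro = right_obj[run, t]
            dF_obj = F_obj[lo] - F_obj[ro]
            dF_feat = 0.0
            for i in range(m):
                dF_feat += F_feat[i, feat_idx[lo, i]] - F_feat[i, feat_idx[ro, i]]
            feat_term = C_F * dF_feat / m
            obj_term = C_O * dF_obj
            p_ove = 0.5
            if model == 0:
                if scale_whole == 1:
                    z = (obj_term + feat_term) / sigma
                    z_o = obj_term / sigma
                    z_f = feat_term / sigma
                else:
                    z = obj_term + feat_term / sigma
                    z_o = obj_term
                    z_f = feat_term / sigma
                p_left = 1.0 / (1.0 + np.exp(-min(max(z, -35.0), 35.0)))
                p_left_o = 1.0 / (1.0 + np.exp(-min(max(z_o, -35.0), 35.0)))
                p_left_f = 1.0 / (1.0 + np.exp(-min(max(z_f, -35.0), 35.0)))
                cho_left = u_choice[run, t] < p_left
                aux_o_left = u_aux_o[run, t] < p_left_o
                aux_f_left = u_aux_f[run, t] < p_left_f
            else:
                so = C_O * abs(dF_obj)
                sf = C_F * abs(dF_feat) / m
                if scale_whole == 1:
                    zs = (so - sf) / sigma
                else:
                    zs = so - sf / sigma
                p_ove = 1.0 / (1.0 + np.exp(-min(max(zs, -35.0), 35.0)))
                ove_selected = u_select[run, t] < p_ove
                if ove_selected:
                    z = dF_obj / sigma
                else:
                    z = dF_feat / (m * sigma)
                p_left = 1.0 / (1.0 + np.exp(-min(max(z, -35.0), 35.0)))
                cho_left = u_choice[run, t] < p_left
                aux_o_left = ove_selected  # reused as the selection flag
                aux_f_left = False
            if cho_left:
                co, uo = lo, ro
                r = r_left[run, t]
            else:
                co, uo = ro, lo
                r = r_right[run, t]
            out_choice[run, t] = 0 if cho_left else 1

            # --- value-synapse plasticity (chosen pools; rest decay) ---
            r_unc = r_right[run, t] if cho_left else r_left[run, t]
            old = F_obj[co]
            if r == 1:
                F_obj[co] = old + qpv * (1.0 - old)
            else:
                F_obj[co] = old - qmv * old
            if full_fb == 1:
                old = F_obj[uo]
                if r_unc == 1:
                    F_obj[uo] = old + qpv * (1.0 - old)
                else:
                    F_obj[uo] = old - qmv * old
            for k in range(D):
                if k != co and not (full_fb == 1 and k == uo):
                    F_obj[k] -= qd * (F_obj[k] - 0.5)
            for i in range(m):
                cf = feat_idx[co, i]
                uf = feat_idx[uo, i]
                updated = cf != uf  # unique-feature rule
                if updated:
                    old = F_feat[i, cf]
                    if r == 1:
                        F_feat[i, cf] = old + qpv * (1.0 - old)
                    else:
                        F_feat[i, cf] = old - qmv * old
                upd_u = full_fb == 1 and cf != uf
                if upd_u:
                    old = F_feat[i, uf]
                    if r_unc == 1:
                        F_feat[i, uf] = old + qpv * (1.0 - old)
                    else:
                        F_feat[i, uf] = old - qmv * old
                for j in range(n):
                    if updated and j == cf:
                        continue
                    if upd_u and j == uf:
                        continue
                    F_feat[i, j] -= qd * (F_feat[i, j] - 0.5)

            # --- connection plasticity ---
            if model == 0:
                o_agree = aux_o_left == cho_left
                f_agree = aux_f_left == cho_left
                if o_agree:
                    if r == 1:
                        C_O = C_O + qpc * (1.0 - C_O)
                    else:
                        C_O = C_O - qmc * C_O
                else:
                    C_O -= qd * (C_O - 0.5)
                if f_agree:
                    if r == 1:
                        C_F = C_F + qpc * (1.0 - C_F)
                    else:
                        C_F = C_F - qmc * C_F
                else:
                    C_F -= qd * (C_F - 0.5)
            else:
                if aux_o_left:  # OVE selected
                    if r == 1:
                        C_O = C_O + qpc * (1.0 - C_O)
                    else:
                        C_O = C_O - qmc * C_O
                    C_F -= qd * (C_F - 0.5)
                else:
                    if r == 1:
                        C_F = C_F + qpc * (1.0 - C_F)
                    else:
                        C_F = C_F - qmc * C_F
                    C_O -= qd * (C_O - 0.5)

            # --- trace ---
            cw = c_weights[sched_of[t]]
            s_o = 0.0
            for k in range(D):
                s_o += cw[k] * F_obj[k]
            s_o = 2.0 * s_o / norm
            # feature-based estimates via the odds combination
            s_f = 0.0
            for k in range(D):
                num = 1.0
                comp = 1.0
                for i in range(m):
                    v = F_feat[i, feat_idx[k, i]]
                    if v < 1e-6:
                        v = 1e-6
                    if v > 1.0 - 1e-6:
                        v = 1.0 - 1e-6
                    num *= v
                    comp *= 1.0 - v
                s_f += cw[k] * (num / (num + comp))
            s_f = 2.0 * s_f / norm
            trace_sums[t, 0] += C_O
            trace_sums[t, 1] += C_F
            trace_sums[t, 2] += s_o
            trace_sums[t, 3] += s_f
            trace_sums[t, 4] += p_ove
            trace_sums[t, 5] += r


def simulate_network(
    model: str,
    design: SessionDesign,
    params: Optional[NetworkParams] = None,
    n_runs: int = 200,
    seed: int = 0,
    return_logs: bool = False,
) -> NetworkTrace | Tuple[NetworkTrace, pd.DataFrame]:
    """Simulate a network model over a task design.

    Returns run-averaged trajectories of the connection strengths, the
    differential signals of the two value sets, the OVE-selection
    probability (HDML), and harvested reward.  With ``return_logs=True``
    also returns standard trial logs (one simulated subject per run) for
    downstream model fitting.
    """
    if model.lower() not in ("pdml", "hdml"):
        raise ValueError("model must be 'pdml' or 'hdml'")
    params = params or NetworkParams()
    space = design.space
    D = space.n_objects
    m, n = space.m, space.n
    T = design.total_trials
    R = n_runs
    rng = np.random.default_rng(seed)

    pairs = _pair_pool(design)
    pair_arr = np.array(
        [
            (np.ravel_multi_index(a, space.shape), np.ravel_multi_index(b, space.shape))
            for a, b in pairs
        ],
        dtype=np.int64,
    )
    idx = rng.integers(len(pairs), size=(R, T))
    swap = rng.random((R, T)) < 0.5
    left = np.where(swap, pair_arr[idx, 1], pair_arr[idx, 0])
    right = np.where(swap, pair_arr[idx, 0], pair_arr[idx, 1])

    # per-trial truth and outcome draws
    sess = np.repeat(np.arange(1, design.sessions + 1), design.trials_per_session)
    trial = np.tile(np.arange(1, design.trials_per_session + 1), design.sessions)
    p_by_trial = np.stack(
        [design.trial_p(sess[t], trial[t]) for t in range(T)]
    )  # (T, D)
    sched_ids = [design.schedule_id(sess[t], trial[t]) for t in range(T)]
    uniq = sorted(set(sched_ids))
    sched_of = np.array([uniq.index(s) for s in sched_ids], dtype=np.int64)
    c_weights = np.stack(
        [
            _sign_weights(p_by_trial[sched_ids.index(u)])
            for u in uniq
        ]
    )
    r_left = (rng.random((R, T)) < p_by_trial[np.arange(T), left]).astype(np.int64)
    r_right = (rng.random((R, T)) < p_by_trial[np.arange(T), right]).astype(np.int64)

    feat_idx = np.array(list(np.ndindex(space.shape)), dtype=np.int64)
    trace_sums = np.zeros((T, 6))
    out_choice = np.empty((R, T), dtype=np.int8)
    _sim_network(
        0 if model.lower() == "pdml" else 1,
        1 if params.scale_whole_logit else 0,
        1 if design.full_feedback else 0,
        left,
        right,
        r_left,
        r_right,
        rng.random((R, T)),
        rng.random((R, T)),
        rng.random((R, T)),
        rng.random((R, T)),
        feat_idx,
        c_weights,
        sched_of,
        m,
        n,
        D,
        params.q_plus_V,
        params.q_minus_V,
        params.q_plus_C,
        params.q_minus_C,
        params.q_d,
        params.sigma,
        trace_sums,
        out_choice,
    )
    avg = trace_sums / R
    chosen = np.where(out_choice == 0, left, right)
    reward = np.where(out_choice == 0, r_left, r_right)
    trace = NetworkTrace(
        C_O=avg[:, 0],
        C_F=avg[:, 1],
        S_O=avg[:, 2],
        S_F=avg[:, 3],
        p_select_OVE=avg[:, 4],
        reward=reward.mean(axis=0),
    )
    if not return_logs:
        return trace
    tok = np.array([space.token(o) for o in space.objects()])
    frames = []
    for run in range(R):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"{model.lower()}-{run:03d}",
                    "experiment": design.experiment,
                    "session": sess,
                    "trial": trial,
                    "block": (
                        np.ones(T, dtype=int)
                        if design.L is None
                        else (trial - 1) // design.L + 1
                    ),
                    "schedule_id": sched_ids,
                    "left_object": tok[left[run]],
                    "right_object": tok[right[run]],
                    "choice": np.where(out_choice[run] == 0, "L", "R"),
                    "chosen_object": tok[chosen[run]],
                    "reward": reward[run].astype(int),
                    "reward_left": (
                        r_left[run].astype(int) if design.full_feedback else pd.NA
                    ),
                    "reward_right": (
                        r_right[run].astype(int) if design.full_feedback else pd.NA
                    ),
                },
                columns=TRIAL_LOG_COLUMNS,
            )
        )
    return trace, pd.concat(frames, ignore_index=True)


def sweep_environments(
    model: str,
    matrices: Sequence[RewardMatrix],
    L_grid: Sequence[int],
    params: Optional[NetworkParams] = None,
    n_runs: int = 100,
    trials: int = 384,
    seed: int = 0,
) -> pd.DataFrame:
    """Performance and arbitration summaries over environment/volatility grids.

    For each (matrix, block length) cell the network is simulated on a
    reversal design; the table reports mean harvested reward, terminal
    ``C_F - C_O``, and mean ``W_F - W_O`` with s.e. over runs (the trace
    means are across runs, so the s.e. columns use the run count).
    """
    from .environments import generalizability_index
    from .tasks import build_reversal_design

    rng = np.random.default_rng(seed)
    rows = []
    for mat in matrices:
        g = generalizability_index(mat).g
        for L in L_grid:
            design = build_reversal_design(
                mat, L=L, trials_per_session=trials, sessions=1
            )
            trace = simulate_network(
                model,
                design,
                params=params,
                n_runs=n_runs,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "model": model,
                    "g": g,
                    "L": L,
                    "D": mat.space.n_objects,
                    "performance": trace.performance,
                    "C_F_minus_C_O": float(trace.C_F[-1] - trace.C_O[-1]),
                    "W_F_minus_W_O": float((trace.W_F - trace.W_O).mean()),
                }
            )
    return pd.DataFrame(rows)


def mean_field_trajectory(
    events: Sequence[str], q_plus: float, q_minus: float, q_d: float, F0: float = 0.5
) -> np.ndarray:
    """Deterministic strength trajectory under a sequence of plasticity events.

    ``events`` contains 'pot', 'dep', or 'decay' per trial.
    """
    F = F0
    out = np.empty(len(events))
    for k, ev in enumerate(events):
        if ev == "pot":
            F = F + q_plus * (1.0 - F)
        elif ev == "dep":
            F = F - q_minus * F
        elif ev == "decay":
            F = F - q_d * (F - 0.5)
        else:
            raise ValueError(f"unknown event {ev!r}")
        out[k] = F
    return out


def binary_synapse_trajectory(
    events: Sequence[str],
    q_plus: float,
    q_minus: float,
    q_d: float,
    n_synapses: int = 10_000,
    seed: int = 0,
    F0: float = 0.5,
) -> np.ndarray:
    """Explicit binary-synapse simulation of one pool.

    Each of ``n_synapses`` synapses is strong or weak; potentiation flips
    each weak synapse with probability q+, depression flips each strong one
    with probability q-, and decay moves the pool toward half strong/half
    weak at rate q_d.  Returns the fraction of strong synapses per event;
    its expectation is the mean-field trajectory.
    """
    rng = np.random.default_rng(seed)
    strong = rng.random(n_synapses) < F0
    out = np.empty(len(events))
    for k, ev in enumerate(events):
        u = rng.random(n_synapses)
        if ev == "pot":
            strong = strong | (~strong & (u < q_plus))
        elif ev == "dep":
            strong = strong & ~(strong & (u < q_minus))
        elif ev == "decay":
            # each synapse relaxes toward the neutral state with prob q_d
            flip_down = strong & (u < q_d * 0.5)
            flip_up = ~strong & (u < q_d * 0.5)
            strong = (strong & ~flip_down) | flip_up
        else:
            raise ValueError(f"unknown event {ev!r}")
        out[k] = strong.mean()
    return out
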