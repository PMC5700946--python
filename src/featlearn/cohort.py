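"""Synthetic study cohorts: simulated subjects with known generating models.

Produces complete datasets — trial logs plus estimation records — for whole
cohorts of simulated subjects, each governed by a specified RL model with
parameters drawn from the validation ranges (learning rate 0.05-0.4, decay
0.005-0.04, choice stochasticity 0.05-0.4).  Estimation records are the
agent's own internal object values (object models) or the odds combination
of its feature values (feature models), perturbed with grid-snapped Gaussian
report noise.  Everything is reproducible from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .environments import FeatureSpace
from .models import (
    ModelSpec,
    ParamVector,
    TRIAL_LOG_COLUMNS,
    _p_left,
    _step,
    simulate_agent,
)
from .tasks import ESTIMATION_GRID, SessionDesign

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_switching_cohort",
    "value_snapshots",
]

ESTIMATES_COLUMNS = [
    "subject_id",
    "experiment",
    "session",
    "estimation_block",
    "object",
    "estimate_percent",
]

#: default parameter ranges of the validation grid
PARAM_RANGES = {"alpha": (0.05, 0.4), "d": (0.005, 0.04), "sigma": (0.05, 0.4)}


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n_subjects: int
    design: SessionDesign
    model_specs: Sequence[ModelSpec]  # cycled over subjects (mixture)
    param_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(PARAM_RANGES)
    )
    estimation_noise_sd: float = 10.0  # percentage points
    seed: int = 0


def _draw_params(
    spec: ModelSpec, ranges, m: int, rng: np.random.Generator
) -> ParamVector:
    alpha = rng.uniform(*ranges["alpha"])
    sigma = rng.uniform(*ranges["sigma"])
    d = rng.uniform(*ranges["d"]) if spec.decay else 0.0
    pv = ParamVector(alpha_rew=alpha, alpha_unr=alpha, d=d, sigma=sigma, bias=0.0)
    if spec.representation == "feature":
        pv.w = np.full((1, m), 1.0 / sigma)
    if spec.attentional:
        pv.alpha_feature = np.full(m, alpha)
    return pv


def value_snapshots(
    log: pd.DataFrame,
    spec: ModelSpec,
    params: ParamVector,
    space: FeatureSpace,
    at: Sequence[Tuple[int, int]],
) -> Dict[Tuple[int, int], np.ndarray]:
    """Replay a trial log and capture internal object values.

    ``at`` lists (session, trial) positions; the snapshot is taken after the
    listed trial's update.  Object models report their object values
    directly; feature models report the odds combination of their feature
    values.  The replay uses the same compiled update step as simulation and
    likelihood evaluation.
    """
    want = set(at)
    V_obj = np.full(space.n_objects, 0.5)
    V_feat = np.full((space.m, space.n), 0.5)
    m = space.m
    a_rew, a_unr = params.learning_rates(spec, m)
    d = float(params.d if spec.decay else 0.0)
    out: Dict[Tuple[int, int], np.ndarray] = {}
    prev_sess = None
    rep = 0 if spec.representation == "object" else 1
    for row in log.itertuples():
        if spec.reset_sessions and row.session != prev_sess:
            V_obj[:] = 0.5
            V_feat[:] = 0.5
        prev_sess = row.session
        lf = np.asarray(space.parse_token(row.left_object), dtype=np.int64)
        rf = np.asarray(space.parse_token(row.right_object), dtype=np.int64)
        lo = int(np.ravel_multi_index(lf, space.shape))
        ro = int(np.ravel_multi_index(rf, space.shape))
        cho_is_left = row.choice == "L"
        r_cho = int(row.reward)
        if spec.full_feedback:
            r_unc = int(row.reward_right if cho_is_left else row.reward_left)
        else:
            r_unc = 0
        _step(
            rep,
            1 if spec.coupling == "coupled" else 0,
            1 if spec.decay else 0,
            1 if spec.full_feedback else 0,
            1 if spec.update_shared else 0,
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
        )
        key = (int(row.session), int(row.trial))
        if key in want:
            if rep == 0:
                out[key] = V_obj.copy()
            else:
                vf = np.clip(V_feat, 1e-6, 1 - 1e-6)
                num = np.ones(space.shape)
                comp = np.ones(space.shape)
                for i in range(m):
                    shape = [1] * m
                    shape[i] = space.n
                    num = num * vf[i].reshape(shape)
                    comp = comp * (1.0 - vf[i]).reshape(shape)
                out[key] = (num / (num + comp)).ravel()
    return out


def _snap_to_grid(values_percent: np.ndarray) -> np.ndarray:
    grid = ESTIMATION_GRID.astype(float)
    idx = np.argmin(
        np.abs(values_percent[:, None] - grid[None, :]), axis=1
    )
    return grid[idx]


def generate_cohort(
    cohort: CohortSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a cohort; returns (trial log, estimates, manifest).

    Subjects cycle through ``model_specs``; per-subject parameters are drawn
    from the cohort's ranges.  Estimation records exist only for designs
    with estimation blocks.  The manifest records every per-subject seed,
    spec, and parameter draw.
    """
    rng = np.random.default_rng(cohort.seed)
    logs: List[pd.DataFrame] = []
    ests: List[pd.DataFrame] = []
    manifest = {"seed": cohort.seed, "subjects": []}
    design = cohort.design
    space = design.space
    tokens = [space.token(o) for o in design.objects()]
    for s in range(cohort.n_subjects):
        spec = cohort.model_specs[s % len(cohort.model_specs)]
        params = _draw_params(spec, cohort.param_ranges, space.m, rng)
        sim_seed = int(rng.integers(2**31 - 1))
        subject_id = f"sub-{cohort.seed:04d}-{s:03d}"
        log = simulate_agent(design, spec, params, seed=sim_seed, subject_id=subject_id)
        logs.append(log)
        manifest["subjects"].append(
            {
                "subject_id": subject_id,
                "model": spec.name,
                "seed": sim_seed,
                "alpha": params.alpha_rew,
                "d": params.d,
                "sigma": params.sigma,
            }
        )
        if design.estimation_after:
            at = [
                (sess, t)
                for sess in range(1, design.sessions + 1)
                for t in design.estimation_after
            ]
            snaps = value_snapshots(log, spec, params, space, at)
            obj_idx = [
                np.ravel_multi_index(space.parse_token(t), space.shape)
                for t in tokens
            ]
            rows = []
            for sess in range(1, design.sessions + 1):
                for b, t in enumerate(design.estimation_after, start=1):
                    v = snaps[(sess, t)][obj_idx] * 100.0
                    noisy = v + rng.normal(0.0, cohort.estimation_noise_sd, v.size)
                    snapped = _snap_to_grid(noisy)
                    for tok, e in zip(tokens, snapped):
                        rows.append(
                            {
                                "subject_id": subject_id,
                                "experiment": design.experiment,
                                "session": sess,
                                "estimation_block": b
                                + (sess - 1) * len(design.estimation_after),
                                "object": tok,
                                "estimate_percent": e,
                            }
                        )
            ests.append(pd.DataFrame(rows, columns=ESTIMATES_COLUMNS))
    trials = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=TRIAL_LOG_COLUMNS)
    )
    estimates = (
        pd.concat(ests, ignore_index=True)
        if ests
        else pd.DataFrame(columns=ESTIMATES_COLUMNS)
    )
    return trials, estimates, manifest


def generate_switching_cohort(
    cohort: CohortSpec, switch_trial: int
) -> pd.DataFrame:
    """Cohort of agents that act feature-based, then object-based.

    Both representations observe every outcome; choices are driven by the
    feature values before ``switch_trial`` (within each session) and by the
    object values from it onward.  Used to validate transition analyses.
    """
    if not 1 <= switch_trial <= cohort.design.trials_per_session + 1:
        raise ValueError("switch_trial outside the session")
    rng = np.random.default_rng(cohort.seed)
    design = cohort.design
    space = design.space
    m = space.m
    feat_spec = ModelSpec(
        "feature",
        "uncoupled",
        decay=True,
        full_feedback=design.full_feedback,
        reset_sessions=True,
    )
    obj_spec = ModelSpec(
        "object",
        "uncoupled",
        decay=True,
        full_feedback=design.full_feedback,
        reset_sessions=True,
    )
    from .tasks import generate_trial_stream

    logs = []
    tok = np.array([space.token(o) for o in space.objects()])
    for s in range(cohort.n_subjects):
        params = _draw_params(feat_spec, cohort.param_ranges, m, rng)
        w = params.weights(m, 1)[0]
        stream = generate_trial_stream(design, int(rng.integers(2**31 - 1)))
        u_choice = rng.random(design.total_trials)
        V_obj = np.full(space.n_objects, 0.5)
        V_feat = np.full((m, space.n), 0.5)
        a_rew, a_unr = params.learning_rates(feat_spec, m)
        d = float(params.d)
        choices = np.empty(design.total_trials, dtype=np.int64)
        prev_sess = 0
        for t in range(design.total_trials):
            if stream["session"][t] != prev_sess:
                V_obj[:] = 0.5
                V_feat[:] = 0.5
            prev_sess = stream["session"][t]
            lo = int(stream["left"][t])
            ro = int(stream["right"][t])
            lf = np.asarray(
                np.unravel_index(lo, space.shape), dtype=np.int64
            )
            rf = np.asarray(
                np.unravel_index(ro, space.shape), dtype=np.int64
            )
            use_feature = stream["trial"][t] < switch_trial
            if use_feature:
                p_left = _p_left(
                    1, V_obj, V_feat, lo, ro, lf, rf, params.sigma, 0.0, w, m
                )
            else:
                p_left = _p_left(
                    0, V_obj, V_feat, lo, ro, lf, rf, params.sigma, 0.0, w, m
                )
            cho_is_left = u_choice[t] < p_left
            choices[t] = 0 if cho_is_left else 1
            r_cho = int(
                stream["r_left"][t] if cho_is_left else stream["r_right"][t]
            )
            r_unc = int(
                stream["r_right"][t] if cho_is_left else stream["r_left"][t]
            )
            # keep both representations learning throughout
            for rep in (0, 1):
                _step(
                    rep,
                    0,
                    1,
                    1 if design.full_feedback else 0,
                    0,
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
                )
        chosen = np.where(choices == 0, stream["left"], stream["right"])
        reward = np.where(choices == 0, stream["r_left"], stream["r_right"])
        logs.append(
            pd.DataFrame(
                {
                    "subject_id": f"switch-{cohort.seed:04d}-{s:03d}",
                    "experiment": design.experiment,
                    "session": stream["session"],
                    "trial": stream["trial"],
                    "block": stream["block"],
                    "schedule_id": stream["schedule_id"],
                    "left_object": tok[stream["left"]],
                    "right_object": tok[stream["right"]],
                    "choice": np.where(choices == 0, "L", "R"),
                    "chosen_object": tok[chosen],
                    "reward": reward.astype(int),
                    "reward_left": (
                        stream["r_left"].astype(int)
                        if design.full_feedback
                        else pd.NA
                    ),
                    "reward_right": (
                        stream["r_right"].astype(int)
                        if design.full_feedback
                        else pd.NA
                    ),
                },
                columns=TRIAL_LOG_COLUMNS,
            )
        )
    return pd.concat(logs, ignore_index=True)
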