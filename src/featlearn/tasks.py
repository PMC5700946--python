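"""Trial, block, and schedule structure of the four choice experiments.

Experiments 1 and 2 are dynamic two-feature tasks over four colored shapes
(2 x 2 space): the reward schedule is fixed for 48-trial blocks, reverses the
informative feature between consecutive blocks, and changes the secondary
feature assignment every four blocks (super-blocks).  Experiment 1 uses
generalizable schedules built from {0.9, 0.7, 0.3, 0.1}; Experiment 2 uses
non-generalizable permutations of the same probabilities.

Experiments 3 and 4 are static tasks over 3 x 3 and 4 x 4 spaces with reward
feedback for both presented objects, objects with p = 0.5 excluded, and
interleaved estimation blocks where per-object reward-probability estimates
are reported on a 5-95% grid in 10% steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .environments import FeatureSpace, RewardMatrix

__all__ = [
    "SessionDesign",
    "EXP3_MATRIX",
    "EXP4_MATRIX",
    "build_exp12_design",
    "build_exp34_design",
    "build_reversal_design",
    "sample_pair",
    "generate_trial_stream",
    "analyzed_trial_count",
    "drop_burn_in",
    "ESTIMATION_GRID",
]

BLOCK_LENGTH = 48
ESTIMATION_GRID = np.arange(5, 96, 10)  # percent

# ---------------------------------------------------------------------------
# Static reward matrices for Experiments 3 and 4.
#
# The original experiments' exact reward tables are not available as
# numbers, so these are synthetic stand-ins constructed by search to
# satisfy every documented design constraint:
# rows (non-informative feature) have mean exactly 0.5; columns (informative
# feature) have distinct means spanning 0.25-0.75; exactly one object (Exp 3)
# or four objects (Exp 4) sit at p = 0.5 and are excluded from play; the
# informative feature is predictive on average but with rank violations; and
# the generalizability index (Pearson) equals the printed 0.57 and 0.76.
# Axis 0 is the non-informative feature, axis 1 the informative one.
# ---------------------------------------------------------------------------

EXP3_MATRIX = np.array(
    [
        [0.29, 0.50, 0.71],
        [0.20, 0.87, 0.43],
        [0.45, 0.12, 0.93],
    ]
)

EXP4_MATRIX = np.array(
    [
        [0.25, 0.50, 0.71, 0.54],
        [0.56, 0.05, 0.50, 0.89],
        [0.09, 0.50, 0.69, 0.72],
        [0.10, 0.55, 0.50, 0.85],
    ]
)


@dataclass
class SessionDesign:
    """Block/schedule scaffolding of one experiment for one subject."""

    experiment: int
    space: FeatureSpace
    informative_feature: int
    trials_per_session: int
    sessions: int
    full_feedback: bool
    # Experiments 1/2: ordered schedule ids per session and the schedule table
    L: Optional[int] = None
    blocks: Optional[List[List[str]]] = None
    schedules: Optional[Dict[str, np.ndarray]] = None
    # Experiments 3/4 (and generic reversal designs): static matrix
    matrix: Optional[RewardMatrix] = None
    used_objects: Optional[List[Tuple[int, ...]]] = None
    estimation_after: Optional[List[int]] = None
    estimation_grid: np.ndarray = field(
        default_factory=lambda: ESTIMATION_GRID.copy()
    )
    # generic reversal designs: per-block schedule cycle (arrays of flat p)
    schedule_cycle: Optional[List[np.ndarray]] = None

    @property
    def total_trials(self) -> int:
        return self.trials_per_session * self.sessions

    def objects(self) -> List[Tuple[int, ...]]:
        if self.used_objects is not None:
            return list(self.used_objects)
        return list(self.space.objects())

    def trial_p(self, session: int, trial: int) -> np.ndarray:
        """Flat per-object reward probabilities in force on a given trial.

        ``session`` and ``trial`` are 1-based; the trial index is within
        session.
        """
        if self.matrix is not None and self.schedule_cycle is None:
            return self.matrix.flat_p
        block0 = (trial - 1) // self.L  # 0-based within session
        if self.schedule_cycle is not None:
            cyc = self.schedule_cycle
            return cyc[block0 % len(cyc)]
        sched_id = self.blocks[session - 1][block0]
        return self.schedules[sched_id].ravel()

    def schedule_id(self, session: int, trial: int) -> str:
        if self.matrix is not None and self.schedule_cycle is None:
            return "static"
        block0 = (trial - 1) // self.L
        if self.schedule_cycle is not None:
            return f"cycle{block0 % len(self.schedule_cycle)}"
        return self.blocks[session - 1][block0]


def _exp12_schedule(
    kind: str, pref_inf: int, pref_sec: int, informative_feature: int
) -> np.ndarray:
    """One 2x2 reward schedule.

    Generalizable: the preferred informative instance gets {0.9, 0.7}, the
    other {0.3, 0.1}, with the larger value on the preferred secondary
    instance.  Non-generalizable: informative-instance means are {0.6, 0.4}
    and secondary means {0.5, 0.5}, with rank-order violations (e.g. the
    preferred informative instance holds both the best and the worst object).
    """
    p = np.empty((2, 2))
    a, b = pref_inf, pref_sec
    if kind == "generalizable":
        p[a, b], p[a, 1 - b] = 0.9, 0.7
        p[1 - a, b], p[1 - a, 1 - b] = 0.3, 0.1
    elif kind == "non-generalizable":
        p[a, b], p[a, 1 - b] = 0.9, 0.3
        p[1 - a, 1 - b], p[1 - a, b] = 0.7, 0.1
    else:
        raise ValueError(f"unknown environment type {kind!r}")
    if informative_feature == 1:
        p = p.T
    return p


def _schedule_name(kind: str, pref_inf: int, pref_sec: int) -> str:
    inf = "RB"[pref_inf]
    if kind == "generalizable":
        return inf + "st"[pref_sec]
    return inf.lower() + str(pref_sec + 1)


def build_exp12_design(
    environment_type: str = "generalizable",
    informative_feature: int = 0,
    seed: int = 0,
) -> SessionDesign:
    """Design of Experiment 1 (generalizable) or 2 (non-generalizable).

    Two sessions of 384 trials in 48-trial blocks; consecutive blocks reverse
    the preferred informative-feature instance, and the secondary assignment
    flips at every 4-block super-block boundary.  The starting assignments
    are randomized by ``seed``.
    """
    rng = np.random.default_rng(seed)
    start_inf = int(rng.integers(2))
    start_sec = int(rng.integers(2))
    schedules: Dict[str, np.ndarray] = {}
    blocks: List[List[str]] = []
    seq: List[str] = []
    for sb in range(4):  # 4 super-blocks of 4 blocks across both sessions
        sec = (start_sec + sb) % 2
        for k in range(4):
            inf = (start_inf + k) % 2
            name = _schedule_name(environment_type, inf, sec)
            schedules[name] = _exp12_schedule(
                environment_type, inf, sec, informative_feature
            )
            seq.append(name)
    blocks = [seq[:8], seq[8:]]
    experiment = 1 if environment_type == "generalizable" else 2
    return SessionDesign(
        experiment=experiment,
        space=FeatureSpace(2, 2, 3.0),
        informative_feature=informative_feature,
        trials_per_session=8 * BLOCK_LENGTH,
        sessions=2,
        full_feedback=False,
        L=BLOCK_LENGTH,
        blocks=blocks,
        schedules=schedules,
    )


def build_exp34_design(
    experiment: int = 3,
    informative_feature: int = 1,
    extended_estimation: bool = False,
    matrix: Optional[np.ndarray] = None,
) -> SessionDesign:
    """Design of Experiment 3 (3x3 space) or 4 (4x4 space).

    Static reward matrix, full feedback for both presented objects, and
    objects with p = 0.5 excluded from play.  Estimation blocks fall after
    the printed choice-trial counts for Experiment 3; Experiment 4 uses the
    same positions scaled to its 336-trial sessions.  A transcribed reward
    matrix can be supplied to replace the packaged synthetic stand-in.
    """
    if experiment == 3:
        base = EXP3_MATRIX if matrix is None else np.asarray(matrix, float)
        n, trials = 3, 280
        est = [42, 84, 140, 210, 280]
        est_ext = [21, 42, 63, 84, 140, 210, 252, 280]
    elif experiment == 4:
        base = EXP4_MATRIX if matrix is None else np.asarray(matrix, float)
        n, trials = 4, 336
        est = [50, 101, 168, 252, 336]
        est_ext = [25, 50, 76, 101, 168, 252, 302, 336]
    else:
        raise ValueError("experiment must be 3 or 4")
    p = base.copy()
    if informative_feature == 0:
        p = p.T  # packaged matrices keep the informative feature on axis 1
    space = FeatureSpace(2, n, 2.0)
    mat = RewardMatrix(
        space=space, p=p, informative_feature=informative_feature
    )
    used = [obj for obj in space.objects() if not np.isclose(p[obj], 0.5)]
    return SessionDesign(
        experiment=experiment,
        space=space,
        informative_feature=informative_feature,
        trials_per_session=trials,
        sessions=2,
        full_feedback=True,
        matrix=mat,
        used_objects=used,
        estimation_after=est_ext if extended_estimation else est,
    )


def build_reversal_design(
    matrix: RewardMatrix,
    L: int = BLOCK_LENGTH,
    trials_per_session: int = 8 * BLOCK_LENGTH,
    sessions: int = 1,
    full_feedback: bool = False,
) -> SessionDesign:
    """Generic dynamic design: a matrix alternating with its reversal.

    Every ``L`` trials the assignment of the informative feature reverses
    (the matrix is flipped along the informative axis), mimicking the
    unsignaled reversals of Experiments 1 and 2 for arbitrary environments
    such as morphs between generalizable and non-generalizable matrices.
    """
    inf = matrix.informative_feature or 0
    flipped = np.flip(matrix.p, axis=inf)
    return SessionDesign(
        experiment=0,
        space=matrix.space,
        informative_feature=inf,
        trials_per_session=trials_per_session,
        sessions=sessions,
        full_feedback=full_feedback,
        L=L,
        matrix=matrix,
        schedule_cycle=[matrix.flat_p.copy(), flipped.ravel().copy()],
    )


def _pair_pool(design: SessionDesign) -> List[Tuple[Tuple, Tuple]]:
    objs = design.objects()
    pairs = list(itertools.combinations(objs, 2))
    if design.experiment in (3, 4):
        # presented objects always differ in both features
        pairs = [
            (a, b)
            for a, b in pairs
            if all(ai != bi for ai, bi in zip(a, b))
        ]
    return pairs


def sample_pair(
    design: SessionDesign, rng: np.random.Generator
) -> Tuple[Tuple, Tuple]:
    """Draw one (left, right) object pair uniformly, sides randomized."""
    pairs = _pair_pool(design)
    a, b = pairs[rng.integers(len(pairs))]
    if rng.random() < 0.5:
        a, b = b, a
    return a, b


def generate_trial_stream(design: SessionDesign, seed: int) -> dict:
    """Pregenerate pairs and per-object Bernoulli outcomes for a whole run.

    Outcomes are drawn independently for both presented objects on every
    trial (selection of an object is rewarded only according to its own
    probability), so the stream does not depend on the agent's choices.
    Returns flat arrays of length ``sessions * trials_per_session``.
    """
    rng = np.random.default_rng(seed)
    pairs = _pair_pool(design)
    idx = rng.integers(len(pairs), size=design.total_trials)
    swap = rng.random(design.total_trials) < 0.5
    u_left = rng.random(design.total_trials)
    u_right = rng.random(design.total_trials)

    space = design.space
    T = design.total_trials
    tps = design.trials_per_session
    session = np.repeat(np.arange(1, design.sessions + 1), tps)
    trial = np.tile(np.arange(1, tps + 1), design.sessions)
    left = np.empty(T, dtype=np.intp)
    right = np.empty(T, dtype=np.intp)
    r_left = np.empty(T, dtype=np.int8)
    r_right = np.empty(T, dtype=np.int8)
    block = np.empty(T, dtype=np.intp)
    sched: List[str] = []
    for k in range(T):
        a, b = pairs[idx[k]]
        if swap[k]:
            a, b = b, a
        ia = np.ravel_multi_index(a, space.shape)
        ib = np.ravel_multi_index(b, space.shape)
        left[k], right[k] = ia, ib
        p = design.trial_p(session[k], trial[k])
        r_left[k] = u_left[k] < p[ia]
        r_right[k] = u_right[k] < p[ib]
        block[k] = 1 if design.L is None else (trial[k] - 1) // design.L + 1
        sched.append(design.schedule_id(session[k], trial[k]))
    return {
        "session": session,
        "trial": trial,
        "block": block,
        "schedule_id": np.array(sched),
        "left": left,
        "right": right,
        "r_left": r_left,
        "r_right": r_right,
    }


def analyzed_trial_count(design: SessionDesign) -> int:
    """Trials remaining after the standard burn-in exclusions.

    Experiments 1/2 drop the first 10 trials of each 48-trial block;
    Experiments 3/4 drop the first 30 trials of each session.
    """
    if design.experiment in (1, 2):
        n_blocks = design.sessions * design.trials_per_session // design.L
        return design.total_trials - 10 * n_blocks
    return design.total_trials - 30 * design.sessions


def drop_burn_in(trials, design: SessionDesign):
    """Filter a trial-log DataFrame to the analyzed subset (see above)."""
    if design.experiment in (1, 2):
        within = (trials["trial"] - 1) % design.L
        return trials[within >= 10]
    return trials[trials["trial"] > 30]
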