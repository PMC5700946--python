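"""Reward environments over factorial feature spaces.

An environment assigns a reward probability to every object in an ``n**m``
factorial space (``m`` features, ``n`` instances per feature).  Fully
generalizable environments are built from per-feature odds ratios; partially
generalizable ones are produced by shuffling reward probabilities within the
slices of one "informative" feature.  The generalizability index of an
environment is the correlation between the actual object reward probabilities
and the probabilities reconstructed from feature marginals via a Bayes-rule
odds combination.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FeatureSpace",
    "RewardMatrix",
    "FeatureProfile",
    "EnvironmentSummary",
    "build_generalizable_matrix",
    "feature_marginals",
    "bayes_combine",
    "combine_marginals",
    "shuffle_matrix",
    "generalizability_index",
    "morph_environments",
    "random_environment_sample",
    "environment_with_g",
    "save_environment",
    "load_environment",
]

#: clamp applied before forming odds ratios from probabilities
_EPS = 1e-6


@dataclass(frozen=True)
class FeatureSpace:
    """A factorial stimulus space: ``m`` features with ``n`` instances each.

    ``x`` is the maximum odds ratio assigned to a feature instance; the
    per-feature odds-ratio grid runs from ``1/x`` to ``x``, equally spaced in
    log space.
    """

    m: int
    n: int
    x: float = 2.0
    labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"need at least one feature, got m={self.m}")
        if self.n < 2:
            raise ValueError(
                f"need at least two instances per feature, got n={self.n}; "
                "a single-instance feature has a degenerate odds-ratio grid"
            )
        if not self.x > 1:
            raise ValueError(f"maximum odds ratio must exceed 1, got x={self.x}")

    @property
    def n_objects(self) -> int:
        """Dimensionality ``D = n**m`` of the environment."""
        return self.n**self.m

    @property
    def shape(self) -> tuple:
        return (self.n,) * self.m

    def objects(self) -> Iterator[tuple]:
        """Iterate over objects as m-tuples of 0-based instance indices."""
        return itertools.product(range(self.n), repeat=self.m)

    def token(self, obj: Sequence[int]) -> str:
        """Serialize an object to its 'i-j-...' token."""
        return "-".join(str(i) for i in obj)

    def parse_token(self, token: str) -> tuple:
        obj = tuple(int(s) for s in token.split("-"))
        if len(obj) != self.m or any(not 0 <= i < self.n for i in obj):
            raise ValueError(f"invalid object token {token!r} for {self}")
        return obj


@dataclass
class RewardMatrix:
    """Reward probabilities per object, with their odds-ratio parentage.

    ``p`` has shape ``(n,)*m`` (row-major, feature 0 slowest).  For matrices
    built directly from odds ratios, ``p = OR/(1+OR)`` holds entrywise; after
    shuffling only the multiset of probabilities is preserved.
    """

    space: FeatureSpace
    p: np.ndarray
    feature_or: Optional[np.ndarray] = None  # (m, n) per-instance odds ratios
    object_or: Optional[np.ndarray] = None  # (n,)*m
    informative_feature: Optional[int] = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.space.shape:
            raise ValueError(
                f"p has shape {self.p.shape}, expected {self.space.shape}"
            )
        if np.any(self.p <= 0) or np.any(self.p >= 1):
            raise ValueError("reward probabilities must lie strictly in (0, 1)")

    @property
    def flat_p(self) -> np.ndarray:
        return self.p.ravel()


@dataclass
class FeatureProfile:
    """Feature marginals and the feature-based reconstruction of a matrix."""

    marginals: np.ndarray  # (m, n)
    estimated: np.ndarray  # (n,)*m


@dataclass
class EnvironmentSummary:
    g: float
    D: int


def _or_grid(n: int, x: float) -> np.ndarray:
    # x**linspace keeps OR=1 exact for odd n (exponent 0)
    return np.power(float(x), np.linspace(-1.0, 1.0, n))


def build_generalizable_matrix(space: FeatureSpace) -> RewardMatrix:
    """Construct the fully generalizable reward matrix of a feature space.

    Each feature carries the odds-ratio grid ``{1/x, ..., x}`` (n terms,
    log-spaced); an object's odds ratio is the product over its feature
    instances and its reward probability is ``OR/(1+OR)``.
    """
    grid = _or_grid(space.n, space.x)
    feature_or = np.tile(grid, (space.m, 1))
    object_or = np.ones(space.shape)
    for i in range(space.m):
        shape = [1] * space.m
        shape[i] = space.n
        object_or = object_or * grid.reshape(shape)
    p = object_or / (1.0 + object_or)
    return RewardMatrix(
        space=space, p=p, feature_or=feature_or, object_or=object_or
    )


def feature_marginals(matrix: RewardMatrix) -> np.ndarray:
    """Per-instance marginal reward probabilities, shape ``(m, n)``.

    The marginal of instance j of feature i is the mean probability over the
    ``n**(m-1)`` objects containing that instance.
    """
    space = matrix.space
    out = np.empty((space.m, space.n))
    for i in range(space.m):
        axes = tuple(k for k in range(space.m) if k != i)
        out[i] = matrix.p.mean(axis=axes) if axes else matrix.p
    return out


def bayes_combine(probs: Sequence[float]) -> float:
    """Combine per-feature reward probabilities into one object probability.

    Uses the odds form of Bayes' rule with a uniform prior:
    ``p = prod(p_i) / (prod(p_i) + prod(1 - p_i))``.  A marginal of exactly
    0 or 1 makes the odds ratio degenerate and is rejected.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0.0) or np.any(probs >= 1.0):
        raise ValueError(
            "bayes_combine requires probabilities strictly inside (0, 1); "
            f"got {probs!r}"
        )
    num = np.prod(probs)
    den = num + np.prod(1.0 - probs)
    return float(num / den)


def combine_marginals(
    marginals: np.ndarray, space: FeatureSpace
) -> np.ndarray:
    """Bayes-combine an ``(m, n)`` marginal table into an ``(n,)*m`` array."""
    marginals = np.asarray(marginals, dtype=float)
    if np.any(marginals <= 0.0) or np.any(marginals >= 1.0):
        raise ValueError("marginals must lie strictly in (0, 1)")
    num = np.ones(space.shape)
    comp = np.ones(space.shape)
    for i in range(space.m):
        shape = [1] * space.m
        shape[i] = space.n
        num = num * marginals[i].reshape(shape)
        comp = comp * (1.0 - marginals[i]).reshape(shape)
    return num / (num + comp)


def feature_profile(matrix: RewardMatrix) -> FeatureProfile:
    """Marginals plus the feature-based reconstruction of a reward matrix."""
    marg = feature_marginals(matrix)
    return FeatureProfile(
        marginals=marg, estimated=combine_marginals(marg, matrix.space)
    )


def shuffle_matrix(
    matrix: RewardMatrix,
    informative_feature: Optional[int],
    seed: int | np.random.Generator,
) -> RewardMatrix:
    """Shuffle reward probabilities within each informative-feature slice.

    Entries are permuted independently inside every slice of the informative
    feature, so that feature's marginal means are preserved exactly while the
    joint structure (and hence generalizability) is degraded.  With
    ``informative_feature=None`` all entries are permuted freely, which is how
    the lowest-generalizability environments are produced.
    """
    space = matrix.space
    rng = np.random.default_rng(seed)
    if informative_feature is None:
        p = rng.permutation(matrix.flat_p).reshape(space.shape)
        return RewardMatrix(space=space, p=p, informative_feature=None)
    if not 0 <= informative_feature < space.m:
        raise ValueError(
            f"informative_feature={informative_feature} out of range for m={space.m}"
        )
    p = np.moveaxis(matrix.p.copy(), informative_feature, 0)
    for j in range(space.n):
        flat = p[j].ravel()
        p[j] = rng.permutation(flat).reshape(p[j].shape)
    p = np.moveaxis(p, 0, informative_feature)
    return RewardMatrix(
        space=space, p=p, informative_feature=informative_feature
    )


def _gamma(a: np.ndarray, b: np.ndarray) -> float:
    """Goodman-Kruskal gamma: (concordant - discordant) / (their sum).

    A rank correlation that ignores tied pairs entirely, so ties in the
    actual probabilities (equal odds-ratio products) that the marginal
    reconstruction happens to break do not count against agreement.
    """
    da = np.sign(a[:, None] - a[None, :])
    db = np.sign(b[:, None] - b[None, :])
    prod = da * db
    concordant = np.sum(prod > 0)
    discordant = np.sum(prod < 0)
    if concordant + discordant == 0:
        return float("nan")
    return float((concordant - discordant) / (concordant + discordant))


def generalizability_index(
    matrix: RewardMatrix, method: str = "rank"
) -> EnvironmentSummary:
    """Correlation between actual and feature-reconstructed probabilities.

    ``method="rank"`` (default) is a tie-insensitive rank correlation
    (Goodman-Kruskal gamma over strictly ordered pairs): it is exactly 1
    whenever the reconstruction reverses no strict ordering of the actual
    probabilities, which makes the fully generalizable boundary exact even
    for spaces whose odds-ratio grid produces tied object probabilities.
    ``"spearman"`` and ``"pearson"`` are also available.  A constant matrix
    has no defined correlation and yields ``g = nan``.
    """
    est = feature_profile(matrix).estimated
    # snap near-ties before ranking: exact ties in p (e.g. OR products equal
    # to 1) must stay tied in the reconstruction despite float rounding
    a = np.round(matrix.flat_p, 10)
    b = np.round(est.ravel(), 10)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return EnvironmentSummary(g=float("nan"), D=matrix.space.n_objects)
    if method == "rank":
        g = _gamma(a, b)
    elif method == "spearman":
        g = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        g = stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return EnvironmentSummary(g=float(g), D=matrix.space.n_objects)


def morph_environments(
    gen: RewardMatrix, nongen: RewardMatrix, lam: float
) -> RewardMatrix:
    """Linear morph ``(1-lam)*p_gen + lam*p_nongen`` between two environments."""
    if gen.space.shape != nongen.space.shape:
        raise ValueError("cannot morph matrices over different feature spaces")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"morphing weight must be in [0, 1], got {lam}")
    p = (1.0 - lam) * gen.p + lam * nongen.p
    return RewardMatrix(
        space=gen.space, p=p, informative_feature=nongen.informative_feature
    )


def random_environment_sample(
    space: FeatureSpace,
    n_samples: int,
    seed: int,
    informative_feature: int = 0,
    method: str = "spearman",
) -> np.ndarray:
    """Generalizability indices of ``n_samples`` independently shuffled matrices."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base = build_generalizable_matrix(space)
    rng = np.random.default_rng(seed)
    out = np.empty(n_samples)
    for k in range(n_samples):
        shuffled = shuffle_matrix(base, informative_feature, rng)
        out[k] = generalizability_index(shuffled, method=method).g
    return out


def environment_with_g(
    space: FeatureSpace,
    target_g: float,
    seed: int,
    n_candidates: int = 200,
    informative_feature: int = 0,
    method: str = "spearman",
) -> RewardMatrix:
    """Search shuffled matrices for one whose g is closest to ``target_g``.

    Draws ``n_candidates`` independent shuffles of the fully generalizable
    matrix — half preserving the informative feature, half unrestricted, so
    that both high- and low-g regions are reachable — and returns the
    candidate minimizing ``|g - target_g|`` (deterministic given the seed).
    ``target_g = 1`` returns the unshuffled matrix itself.
    """
    base = build_generalizable_matrix(space)
    if target_g >= 1.0:
        return base
    rng = np.random.default_rng(seed)
    best, best_err = None, np.inf
    for k in range(n_candidates):
        keep = informative_feature if k % 2 == 0 else None
        cand = shuffle_matrix(base, keep, rng)
        g = generalizability_index(cand, method=method).g
        err = abs(g - target_g)
        if err < best_err:
            best, best_err = cand, err
    return best


def save_environment(matrix: RewardMatrix, path, seed: Optional[int] = None) -> None:
    """Write an environment to JSON (p row-major, feature 0 slowest)."""
    space = matrix.space
    payload = {
        "m": space.m,
        "n": space.n,
        "x": space.x,
        "informative_feature": matrix.informative_feature,
        "p": [float(v) for v in matrix.flat_p],
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_environment(path) -> RewardMatrix:
    with open(path) as fh:
        payload = json.load(fh)
    space = FeatureSpace(m=payload["m"], n=payload["n"], x=payload["x"])
    p = np.asarray(payload["p"], dtype=float).reshape(space.shape)
    return RewardMatrix(
        space=space, p=p, informative_feature=payload.get("informative_feature")
    )
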