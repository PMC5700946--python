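"""Maximum-likelihood fitting of the RL models and its validation.

Fitting minimizes the negative log likelihood of observed choices with a
derivative-free simplex search started from at least 10 randomized initial
conditions.  Bounded parameters (learning rates, decay, choice stochasticity)
are optimized through monotone transforms (logit / log) so the simplex can
never leave the valid region.  Validation follows the simulate-and-refit
logic: agents are simulated over a grid of parameters, refit with every
candidate model, and winners tabulated by BIC (model recovery) alongside the
absolute parameter-estimation error (parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .environments import FeatureSpace
from .models import (
    EncodedTrials,
    ModelSpec,
    ParamVector,
    encode_trials,
    negative_log_likelihood,
    simulate_agent,
)
from .tasks import SessionDesign

__all__ = [
    "FitResult",
    "information_criteria",
    "fit_model",
    "model_recovery",
    "parameter_recovery",
    "timecourse_gof",
]


@dataclass
class FitResult:
    spec: ModelSpec
    params: ParamVector
    nll: float
    aic: float
    bic: float
    k: int
    N: int
    n_starts: int
    converged: bool
    seed: int

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.name,
            "nll": self.nll,
            "nll_per_trial": self.nll / max(self.N, 1),
            "aic": self.aic,
            "bic": self.bic,
            "k": self.k,
            "N": self.N,
            "n_starts": self.n_starts,
            "converged": bool(self.converged),
            "seed": self.seed,
            "alpha_rew": self.params.alpha_rew,
            "alpha_unr": self.params.alpha_unr,
            "sigma": self.params.sigma,
            "bias": self.params.bias,
        }
        if self.spec.decay:
            d["d"] = self.params.d
        if self.params.w is not None:
            d["w"] = np.asarray(self.params.w).tolist()
        if self.params.alpha_feature is not None:
            d["alpha_feature"] = np.asarray(self.params.alpha_feature).tolist()
        return d


def information_criteria(nll: float, k: int, N: int) -> Tuple[float, float]:
    """AIC = 2k + 2*nll; BIC = k*ln(N) + 2*nll."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return 2.0 * k + 2.0 * nll, k * float(np.log(N)) + 2.0 * nll


# -- parameter layout ---------------------------------------------------------

_RATE, _LOG, _FREE = 0, 1, 2


def _layout(spec: ModelSpec, m: int, n_sessions: int):
    """(name, kind) list of free parameters for one model."""
    items: List[Tuple[str, int]] = []
    if spec.attentional:
        items += [(f"alpha_f{i}", _RATE) for i in range(m)]
        items += [("d", _RATE)]
        for s in range(n_sessions):
            items += [(f"w{s}_{i}", _FREE) for i in range(m)]
        items += [("bias", _FREE)]
        return items
    items += [("alpha_rew", _RATE), ("alpha_unr", _RATE)]
    if spec.decay:
        items += [("d", _RATE)]
    if spec.representation == "object":
        items += [("sigma", _LOG)]
    else:
        items += [(f"w0_{i}", _FREE) for i in range(m)]
    items += [("bias", _FREE)]
    return items


def _to_params(
    x: np.ndarray, spec: ModelSpec, m: int, n_sessions: int
) -> ParamVector:
    """Map a transformed-space vector to a ParamVector."""
    items = _layout(spec, m, n_sessions)
    vals: Dict[str, float] = {}
    for (name, kind), xi in zip(items, x):
        if kind == _RATE:
            vals[name] = 1.0 / (1.0 + np.exp(-np.clip(xi, -500.0, 500.0)))
        elif kind == _LOG:
            vals[name] = float(np.exp(xi))
        else:
            vals[name] = float(xi)
    pv = ParamVector(
        alpha_rew=vals.get("alpha_rew", 0.0),
        alpha_unr=vals.get("alpha_unr", 0.0),
        d=vals.get("d", 0.0),
        sigma=vals.get("sigma", 1.0),
        bias=vals.get("bias", 0.0),
    )
    if spec.representation == "feature":
        n_w = n_sessions if spec.attentional else 1
        pv.w = np.array(
            [[vals[f"w{s}_{i}"] for i in range(m)] for s in range(n_w)]
        )
    if spec.attentional:
        pv.alpha_feature = np.array([vals[f"alpha_f{i}"] for i in range(m)])
    return pv


def _sample_start(
    items, rng: np.random.Generator
) -> np.ndarray:
    """Random initial condition, drawn in natural space then transformed."""
    x = np.empty(len(items))
    for k, (name, kind) in enumerate(items):
        if kind == _RATE:
            v = rng.uniform(0.002, 0.08) if name == "d" else rng.uniform(0.02, 0.5)
            x[k] = np.log(v / (1.0 - v))
        elif kind == _LOG:
            x[k] = np.log(rng.uniform(0.03, 0.5))
        elif name == "bias":
            x[k] = rng.uniform(-0.5, 0.5)
        else:  # feature weight
            x[k] = rng.uniform(0.5, 12.0)
    return x


def fit_model(
    trials: pd.DataFrame | EncodedTrials,
    spec: ModelSpec,
    n_starts: int = 10,
    seed: int = 0,
    space: Optional[FeatureSpace] = None,
    maxfev: int = 400,
) -> FitResult:
    """Fit one model by multi-start simplex minimization of the -LL.

    At least 10 randomized initial conditions are used by default; the best
    of all starts is kept.  Deterministic given ``seed``.
    """
    if isinstance(trials, EncodedTrials):
        enc = trials
    else:
        if space is None:
            raise ValueError("space is required when passing a DataFrame")
        enc = encode_trials(trials, space, reset_sessions=spec.reset_sessions)
    m, n_sessions = enc.space.m, enc.n_sessions
    items = _layout(spec, m, n_sessions)
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        pv = _to_params(x, spec, m, n_sessions)
        val = negative_log_likelihood(enc, spec, pv)
        return val if np.isfinite(val) else 1e12

    best_x, best_val, any_ok = None, np.inf, False
    for _ in range(n_starts):
        x0 = _sample_start(items, rng)
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-6},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)
            any_ok = bool(any_ok or res.success or res.fun < 1e11)
    if best_x is None:
        raise RuntimeError(
            f"all {n_starts} optimization starts failed for model {spec.name}"
        )
    params = _to_params(best_x, spec, m, n_sessions)
    k = len(items)
    N = enc.n_trials
    aic, bic = information_criteria(best_val, k, N)
    return FitResult(
        spec=spec,
        params=params,
        nll=best_val,
        aic=aic,
        bic=bic,
        k=k,
        N=N,
        n_starts=n_starts,
        converged=any_ok,
        seed=seed,
    )


def _generating_params(
    spec: ModelSpec, alpha: float, d: float, sigma: float, m: int
) -> ParamVector:
    """Parameters of a simulated agent on the validation grid.

    Feature-based agents receive weights 1/sigma per feature so that their
    choice stochasticity matches the object-based convention.
    """
    pv = ParamVector(
        alpha_rew=alpha, alpha_unr=alpha, d=d, sigma=sigma, bias=0.0
    )
    if spec.representation == "feature":
        pv.w = np.full((1, m), 1.0 / sigma)
    if spec.attentional:
        pv.alpha_feature = np.full(m, alpha)
    return pv


def model_recovery(
    design: SessionDesign,
    specs: Sequence[ModelSpec],
    param_grid: Optional[Dict[str, Sequence[float]]] = None,
    n_reps: int = 10,
    seed: int = 0,
    n_starts: int = 10,
    maxfev: int = 300,
    fit_specs: Optional[Sequence[ModelSpec]] = None,
) -> pd.DataFrame:
    """Simulate-and-refit confusion analysis over a parameter grid.

    For every generating spec and grid cell, ``n_reps`` agents are simulated
    and refit with all candidate specs; the best-BIC winner and the absolute
    learning-rate estimation error of the matching fit are tabulated.
    Default grid spans the validation ranges: learning rate 0.05-0.4, decay
    0.005-0.04, choice stochasticity 0.05-0.4.
    """
    if param_grid is None:
        param_grid = {
            "alpha": [0.05, 0.4],
            "d": [0.005, 0.04],
            "sigma": [0.05, 0.4],
        }
    fit_specs = list(fit_specs if fit_specs is not None else specs)
    rng = np.random.default_rng(seed)
    rows = []
    for gen in specs:
        d_values = param_grid["d"] if gen.decay else [0.0]
        for alpha in param_grid["alpha"]:
            for d in d_values:
                for sigma in param_grid["sigma"]:
                    pv = _generating_params(gen, alpha, d, sigma, design.space.m)
                    for rep in range(n_reps):
                        sim_seed = int(rng.integers(2**31 - 1))
                        log = simulate_agent(design, gen, pv, seed=sim_seed)
                        enc = encode_trials(
                            log, design.space, reset_sessions=gen.reset_sessions
                        )
                        fits = {
                            fs.name: fit_model(
                                enc,
                                fs,
                                n_starts=n_starts,
                                seed=int(rng.integers(2**31 - 1)),
                                maxfev=maxfev,
                            )
                            for fs in fit_specs
                        }
                        winner = min(fits.values(), key=lambda f: f.bic)
                        own = fits.get(gen.name)
                        alpha_err = (
                            abs(own.params.alpha_rew - alpha)
                            if own is not None
                            else np.nan
                        )
                        rows.append(
                            {
                                "generating": gen.name,
                                "alpha": alpha,
                                "d": d,
                                "sigma": sigma,
                                "rep": rep,
                                "winner": winner.spec.name,
                                "recovered": winner.spec.name == gen.name,
                                "alpha_err": alpha_err,
                                "own_bic": own.bic if own else np.nan,
                                "winner_bic": winner.bic,
                            }
                        )
    return pd.DataFrame(rows)


def parameter_recovery(
    design: SessionDesign,
    spec: ModelSpec,
    params: ParamVector,
    n_reps: int = 20,
    seed: int = 0,
    n_starts: int = 10,
    n_trials: Optional[int] = None,
    maxfev: int = 400,
) -> pd.DataFrame:
    """Refit a known generating agent repeatedly; report per-rep estimates."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        log = simulate_agent(
            design, spec, params, seed=int(rng.integers(2**31 - 1))
        )
        if n_trials is not None:
            log = log.iloc[:n_trials]
        fit = fit_model(
            log,
            spec,
            n_starts=n_starts,
            seed=int(rng.integers(2**31 - 1)),
            space=design.space,
            maxfev=maxfev,
        )
        rows.append(
            {
                "rep": rep,
                "alpha_hat": fit.params.alpha_rew,
                "alpha_err": abs(fit.params.alpha_rew - params.alpha_rew),
                "sigma_hat": fit.params.sigma,
                "nll": fit.nll,
            }
        )
    return pd.DataFrame(rows)


def timecourse_gof(
    nll_object: np.ndarray,
    nll_feature: np.ndarray,
    window: int = 20,
    boundary: int = 100,
) -> dict:
    """Early/late contrast of per-trial fit quality between the two models.

    ``nll_object`` and ``nll_feature`` are per-trial -LL streams of the best
    object-based and feature-based fits.  Curves are smoothed with a moving
    average; the contrast is the mean of (nll_object - nll_feature) over
    early trials (1..boundary) minus the same mean over late trials.  A
    positive contrast marks an early-feature / late-object transition.  The
    chance reference is log(2) per trial.
    """
    nll_object = np.asarray(nll_object, float)
    nll_feature = np.asarray(nll_feature, float)
    if nll_object.shape != nll_feature.shape:
        raise ValueError("per-trial -LL streams differ in length")
    T = nll_object.size
    kernel = np.ones(window) / window
    smooth_o = np.convolve(nll_object, kernel, mode="same")
    smooth_f = np.convolve(nll_feature, kernel, mode="same")
    diff = nll_object - nll_feature
    early = diff[:boundary].mean()
    late = diff[boundary:].mean() if boundary < T else np.nan
    return {
        "curve_object": smooth_o,
        "curve_feature": smooth_f,
        "early": float(early),
        "late": float(late),
        "contrast": float(early - late),
        "chance": float(np.log(2.0)),
    }
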