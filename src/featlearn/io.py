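"""Readers and writers for the package's file formats.

Trial logs and estimation records are plain CSV with fixed headers;
environments are JSON (see :mod:`featlearn.environments`); model specs and
parameters are YAML.  All writers use UTF-8, '.' decimals, and no index
column; floats are serialized with 12 significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .cohort import ESTIMATES_COLUMNS
from .environments import FeatureSpace, load_environment, save_environment
from .models import ModelSpec, ParamVector, TRIAL_LOG_COLUMNS

__all__ = [
    "read_trial_log",
    "write_trial_log",
    "read_estimates",
    "write_estimates",
    "spec_from_yaml",
    "params_from_yaml",
    "save_model_yaml",
    "load_environment",
    "save_environment",
]


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


def write_trial_log(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial log missing columns {missing}")
    trials[TRIAL_LOG_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_trial_log(path, space: FeatureSpace | None = None) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    The header must match the documented column order exactly; outcome
    columns must be 0/1; object tokens must parse against ``space`` when one
    is given.  Malformed rows are reported with their row number.
    """
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_LOG_COLUMNS:
        raise FormatError(
            f"unexpected trial-log header {list(df.columns)!r}; "
            f"expected {TRIAL_LOG_COLUMNS!r}"
        )
    bad = ~df["reward"].isin([0, 1])
    if bad.any():
        raise FormatError(
            f"out-of-range reward at row(s) {list(df.index[bad][:5] + 2)}"
        )
    bad = ~df["choice"].isin(["L", "R"])
    if bad.any():
        raise FormatError(
            f"invalid choice at row(s) {list(df.index[bad][:5] + 2)}"
        )
    if space is not None:
        for col in ("left_object", "right_object", "chosen_object"):
            for i, tok in enumerate(df[col]):
                try:
                    space.parse_token(str(tok))
                except ValueError as e:
                    raise FormatError(f"row {i + 2}, column {col}: {e}") from e
    return df


def write_estimates(estimates: pd.DataFrame, path) -> None:
    missing = [c for c in ESTIMATES_COLUMNS if c not in estimates.columns]
    if missing:
        raise FormatError(f"estimates table missing columns {missing}")
    estimates[ESTIMATES_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ESTIMATES_COLUMNS:
        raise FormatError(
            f"unexpected estimates header {list(df.columns)!r}; "
            f"expected {ESTIMATES_COLUMNS!r}"
        )
    return df


def spec_from_yaml(path) -> ModelSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return ModelSpec(**payload.get("spec", payload))


def params_from_yaml(path) -> ParamVector:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    block = payload.get("params", payload)
    if "w" in block and block["w"] is not None:
        block["w"] = np.asarray(block["w"], dtype=float)
    if "alpha_feature" in block and block["alpha_feature"] is not None:
        block["alpha_feature"] = np.asarray(block["alpha_feature"], dtype=float)
    return ParamVector(**block)


def save_model_yaml(spec: ModelSpec, params: ParamVector, path) -> None:
    payload = {
        "spec": {
            "representation": spec.representation,
            "coupling": spec.coupling,
            "decay": spec.decay,
            "attentional": spec.attentional,
            "full_feedback": spec.full_feedback,
            "update_shared": spec.update_shared,
            "reset_sessions": spec.reset_sessions,
        },
        "params": {
            "alpha_rew": float(params.alpha_rew),
            "alpha_unr": float(params.alpha_unr),
            "d": float(params.d),
            "sigma": float(params.sigma),
            "bias": float(params.bias),
            "w": None if params.w is None else np.asarray(params.w).tolist(),
            "alpha_feature": (
                None
                if params.alpha_feature is None
                else np.asarray(params.alpha_feature).tolist()
            ),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
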