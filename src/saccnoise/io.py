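"""File formats: long-format delimited trial files, statistics tables and
configuration snapshots.

Trial files are plain CSV in long format with columns ``trial_id, time_s,
eye_pos_deg, target_pos_deg`` (one row per sample), accompanied by a JSON
sidecar recording the generating configuration and seed.  Statistics tables
are CSV with one row per normalized sample; summary records are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import LoopParameters, PlantParameters
from .profiles import MainSequenceModel
from .stats import TrajectoryStatistics, detect_matrix
from .synth import ConditionConfig, NoiseCoefficients, TrialEnsemble

__all__ = [
    "write_trials",
    "read_trials",
    "write_statistics",
    "read_statistics",
    "config_to_dict",
    "config_from_dict",
]

_TRIAL_COLUMNS = ["trial_id", "time_s", "eye_pos_deg", "target_pos_deg"]


def config_to_dict(config: ConditionConfig) -> dict:
    """Serializable snapshot of a condition configuration."""
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> ConditionConfig:
    d = dict(d)
    d["noise"] = NoiseCoefficients(**d["noise"])
    d["loop"] = LoopParameters(**d["loop"])
    d["plant"] = PlantParameters(**d["plant"])
    ms = dict(d["main_sequence"])
    ms["A_range"] = tuple(ms["A_range"])
    d["main_sequence"] = MainSequenceModel(**ms)
    d["motor_error_bounds"] = tuple(d["motor_error_bounds"])
    return ConditionConfig(**d)


def write_trials(ensemble: TrialEnsemble, path: str | Path, sidecar: bool = True) -> Path:
    """Write an ensemble as a long-format CSV (+ JSON config sidecar)."""
    path = Path(path)
    n, T = ensemble.positions.shape
    df = pd.DataFrame(
        {
            "trial_id": np.repeat(np.arange(n), T),
            "time_s": np.tile(ensemble.time, n),
            "eye_pos_deg": ensemble.positions.ravel(),
            "target_pos_deg": np.repeat(ensemble.motor_errors, T),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        meta = {
            "condition": ensemble.condition,
            "seed": ensemble.seed,
            "n_trials": n,
            "config": config_to_dict(ensemble.config) if ensemble.config else None,
            "planned_amplitudes": [float(a) for a in ensemble.planned_amplitudes],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_trials(path: str | Path) -> TrialEnsemble:
    """Read a long-format trial file back into an ensemble.

    Validates the schema, per-trial time monotonicity and a homogeneous
    sampling rate; saccade landmarks are re-detected from the traces.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[_TRIAL_COLUMNS].isna().any().any():
        bad = int(df[df[_TRIAL_COLUMNS].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}: malformed row at line {bad}")
    groups = df.groupby("trial_id", sort=True)
    lengths = groups.size()
    if lengths.nunique() != 1:
        raise ValueError(
            f"{path}: unequal trial lengths (trial {lengths.idxmin()} is truncated)"
        )
    time = None
    positions, targets = [], []
    for tid, g in groups:
        t = g["time_s"].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: non-monotone time in trial {tid}")
        if time is None:
            time = t
            step = dt[0]
        if not np.allclose(np.diff(t), step, rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: mixed sampling rates (trial {tid})")
        positions.append(g["eye_pos_deg"].to_numpy())
        targets.append(float(g["target_pos_deg"].iloc[0]))
    Y = np.vstack(positions)
    meta_path = path.with_suffix(path.suffix + ".json")
    seed = None
    config = None
    condition = "unknown"
    planned = np.full(len(Y), np.nan)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        seed = meta.get("seed")
        condition = meta.get("condition", condition)
        if meta.get("config"):
            config = config_from_dict(meta["config"])
        if meta.get("planned_amplitudes"):
            planned = np.asarray(meta["planned_amplitudes"], float)
    det = detect_matrix(Y, rate=1.0 / (time[1] - time[0]))
    return TrialEnsemble(
        time=time,
        positions=Y,
        motor_errors=np.asarray(targets, float),
        planned_amplitudes=planned,
        onsets=det["onset"],
        offsets=det["offset"],
        onset_times=det["onset_time"],
        offset_times=det["offset_time"],
        amplitudes=det["amplitude"],
        durations=det["duration"],
        peak_velocities=det["peak_velocity"],
        peak_indices=det["peak_index"],
        condition=condition,
        config=config,
        seed=seed,
    )


def write_statistics(stats: TrajectoryStatistics, path: str | Path) -> Path:
    """Per-sample statistics table (CSV) + summary JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "t_norm": stats.t_norm,
            "y_bar": stats.y_bar,
            "var_y": stats.var_y,
            "cov_ye": stats.cov_ye,
            "rho_ye": stats.rho_ye,
        }
    ).to_csv(path, index=False)
    summary = {
        "A_bar": stats.A_bar,
        "D_bar": stats.D_bar,
        "n_trials": stats.n_trials,
        "mode": stats.mode,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=1))
    return path


def read_statistics(path: str | Path) -> TrajectoryStatistics:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TrajectoryStatistics(
        t_norm=df["t_norm"].to_numpy(),
        y_bar=df["y_bar"].to_numpy(),
        var_y=df["var_y"].to_numpy(),
        cov_ye=df["cov_ye"].to_numpy(),
        A_bar=meta["A_bar"],
        D_bar=meta["D_bar"],
        n_trials=meta["n_trials"],
        mode=meta["mode"],
    )
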