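"""File I/O for trajectories, posterior samples and experiment reports.

Trajectories travel as CSV (columns ``t_s``, ``f_o_cents``, optionally
``se_cents``) with a JSON sidecar holding parameters, perturbation, seed and
stability flag; posterior samples as CSV with one column per parameter plus
the repetition id; summaries, effect sizes and experiment reports as JSON.
All floats are serialized at full precision so round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import EffectSizeReport, PosteriorSamples, PosteriorSummary
from .params import PARAM_NAMES
from .simulate import PerturbationSpec, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_posterior",
    "read_posterior",
    "write_json",
    "read_json",
    "summary_to_json",
    "summary_from_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectory(path: str | Path, traj: Trajectory, se: np.ndarray | None = None) -> Path:
    """Write a trajectory CSV plus a JSON sidecar with its metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t_s": traj.t, "f_o_cents": traj.f_o})
    if se is not None:
        df["se_cents"] = np.asarray(se, dtype=float)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "pert": traj.pert.to_dict() if traj.pert is not None else None,
        "unstable": bool(traj.unstable),
        "meta": traj.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def read_trajectory(path: str | Path) -> tuple[Trajectory, np.ndarray | None]:
    """Read a trajectory CSV (+ sidecar if present); returns (trajectory, se)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "f_o_cents"):
        if col not in df.columns:
            raise ValueError(f"malformed trajectory CSV {path}: missing column {col!r}")
    pert = None
    unstable = False
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        if data.get("pert"):
            pert = PerturbationSpec(**data["pert"])
        unstable = bool(data.get("unstable", False))
        meta = data.get("meta", {})
    traj = Trajectory(
        t=df["t_s"].to_numpy(), f_o=df["f_o_cents"].to_numpy(), pert=pert, unstable=unstable, meta=meta
    )
    se = df["se_cents"].to_numpy() if "se_cents" in df.columns else None
    return traj, se


def write_posterior(path: str | Path, samples: PosteriorSamples) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples.samples.to_csv(path, index=False, float_format="%.17g")
    _sidecar(path).write_text(json.dumps({"observation_id": samples.observation_id}))
    return path


def read_posterior(path: str | Path) -> PosteriorSamples:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PARAM_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"malformed posterior CSV {path}: missing columns {missing}")
    if "repetition" not in df.columns:
        df["repetition"] = 0
    obs_id = ""
    sidecar = _sidecar(path)
    if sidecar.exists():
        obs_id = json.loads(sidecar.read_text()).get("observation_id", "")
    return PosteriorSamples(samples=df, observation_id=obs_id)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def summary_to_json(summary: PosteriorSummary) -> dict:
    return summary.table.to_dict(orient="index")


def summary_from_json(data: dict) -> PosteriorSummary:
    return PosteriorSummary(table=pd.DataFrame(data).T[["median", "ci_low", "ci_high", "sd"]])


def effect_sizes_to_json(report: EffectSizeReport) -> dict:
    return report.table.to_dict(orient="index")
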