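"""Reading and writing the package's on-disk formats.

Everything is plain text: two-column CSV for trajectories and landscapes,
CSV for signal traces and event tables, JSON for distributions, fits and
run manifests, YAML for run configuration.  Write-then-read round trips
preserve values to full float precision (17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fpt import EVENT_COLUMNS, FPTDistribution
from .landscapes import PotentialLandscape, Well
from .simulate import SignalTrace, Trajectory

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_trace", "read_trace",
    "write_events", "read_events",
    "write_distribution", "read_distribution",
    "write_landscape", "read_landscape",
    "write_fit", "load_config", "config_hash",
]

_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing column '{c}' "
                             f"(found {list(df.columns)})")


def _read_csv(path, numeric_cols):
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, numeric_cols, path)
    for c in numeric_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}, line {line}: cannot parse "
                             f"'{df[c][bad.idxmax()]}' in column '{c}'")
        df[c] = converted
    return df


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({"t_s": traj.times, "x_um": traj.positions})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path, trajectory_id: int = 0) -> Trajectory:
    df = _read_csv(path, ["t_s", "x_um"])
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: trajectory needs at least 2 rows")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: non-uniform sampling")
    return Trajectory(frame_interval=float(dt[0]),
                      positions=df["x_um"].to_numpy(),
                      trajectory_id=trajectory_id)


def write_trace(trace: SignalTrace, path) -> None:
    data = {"t_s": trace.times, "value": trace.values}
    if trace.true_states is not None:
        data["true_state"] = trace.true_states
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path) -> SignalTrace:
    df = _read_csv(path, ["t_s", "value"])
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: trace needs at least 2 rows")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: non-uniform sampling")
    states = (df["true_state"].to_numpy(dtype=int)
              if "true_state" in df.columns else None)
    return SignalTrace(frame_interval=float(dt[0]),
                       values=df["value"].to_numpy(), true_states=states)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.rename(columns={"t_fpt": "t_fpt_s"})
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> pd.DataFrame:
    df = _read_csv(path, ["trajectory_id", "start_index", "start_well", "m",
                          "t_fpt_s"])
    _require_columns(df, ["exit_side"], path)
    df = df.rename(columns={"t_fpt_s": "t_fpt"})
    return df[EVENT_COLUMNS if "edge_flag" in df.columns
              else [c for c in EVENT_COLUMNS if c != "edge_flag"]]


def write_distribution(dist: FPTDistribution, path, extra: dict | None = None
                       ) -> None:
    payload = {
        "bin_edges_s": dist.bin_edges.tolist(),
        "density_per_s": dist.density.tolist(),
        "counts": dist.counts.tolist(),
        "n_events": dist.n_events,
        "m": dist.m,
        "label": dist.label,
        "ci_low": None if dist.ci_low is None else dist.ci_low.tolist(),
        "ci_high": None if dist.ci_high is None else dist.ci_high.tolist(),
        "ci_level": dist.ci_level,
        "frame_interval_s": dist.frame_interval,
        "meta": dist.meta,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_distribution(path) -> FPTDistribution:
    p = json.loads(Path(path).read_text())
    return FPTDistribution(
        bin_edges=np.asarray(p["bin_edges_s"]),
        density=np.asarray(p["density_per_s"]),
        counts=np.asarray(p["counts"]),
        n_events=int(p["n_events"]), m=p.get("m"), label=p.get("label", ""),
        ci_low=None if p.get("ci_low") is None else np.asarray(p["ci_low"]),
        ci_high=None if p.get("ci_high") is None
        else np.asarray(p["ci_high"]),
        ci_level=p.get("ci_level"),
        frame_interval=p.get("frame_interval_s"), meta=p.get("meta", {}))


def write_landscape(ls: PotentialLandscape, path_csv, path_json=None) -> None:
    pd.DataFrame({"x": ls.x_grid, "U_kBT": ls.U}).to_csv(
        path_csv, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "exits": list(ls.exits),
        "wells": [{"center": w.center, "depth": w.depth, "width": w.width}
                  for w in ls.wells],
        "boundaries": ls.boundaries.tolist(),
        "label": ls.label,
    }
    if path_json is None:
        path_json = str(path_csv) + ".json"
    Path(path_json).write_text(json.dumps(sidecar, indent=1))


def read_landscape(path_csv, path_json=None) -> PotentialLandscape:
    df = _read_csv(path_csv, ["x", "U_kBT"])
    if path_json is None:
        path_json = str(path_csv) + ".json"
    side = json.loads(Path(path_json).read_text())
    return PotentialLandscape(
        x_grid=df["x"].to_numpy(), U=df["U_kBT"].to_numpy(),
        exits=tuple(side["exits"]),
        wells=[Well(**w) for w in side["wells"]],
        boundaries=np.asarray(side["boundaries"]),
        label=side.get("label", ""))


def write_fit(fit_dict: dict, path, extra: dict | None = None) -> None:
    payload = dict(fit_dict)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


#: allowed keys of a run configuration file, by section
CONFIG_SCHEMA = {
    "mode": str,            # langevin | chain | trace | analyze
    "preset": str,
    "seed": int,
    "n_trajectories": int,
    "n_cycles": int,
    "total_time": float,
    "depths": list,
    "n_boot": int,
    "bins_per_decade": int,
    "window": (str, list),
    "output_dir": str,
    "quiet": bool,
}


def load_config(path) -> dict:
    """Strict YAML run configuration: unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key, val in raw.items():
        if key not in CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config key '{key}' "
                             f"(allowed: {sorted(CONFIG_SCHEMA)})")
        want = CONFIG_SCHEMA[key]
        if want is float and isinstance(val, int):
            val = float(val)
            raw[key] = val
        if not isinstance(val, want):
            raise ValueError(f"{path}: key '{key}' should be "
                             f"{want}, got {type(val).__name__}")
    return raw
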