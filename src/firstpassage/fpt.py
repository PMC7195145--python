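"""First-passage-time events and distributions.

Every recorded position of an exiting trajectory is taken as a fresh start
(the restart rule, valid for Markovian dynamics): an event's first-passage
time is ``t_exit - t_i`` where ``t_exit`` is the time of the first frame
outside the channel.  Events are classed by ``m``, the minimum number of
intermediate wells between the start region and the realised exit, and
pooled over exit sides to form per-m distributions on logarithmic bins with
block-bootstrap (whole-trajectory resampling) confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscapes import PotentialLandscape
from .simulate import Trajectory

__all__ = [
    "FPTEvent",
    "FPTDistribution",
    "EVENT_COLUMNS",
    "extract_fpt_events",
    "extract_fpt_events_ensemble",
    "select_events",
    "build_distribution",
    "bootstrap_ci",
    "events_from_samples",
]

#: Column schema of the events table (one row per FPTEvent).
EVENT_COLUMNS = ["trajectory_id", "start_index", "start_well", "m",
                 "exit_side", "t_fpt", "edge_flag"]


@dataclass(frozen=True)
class FPTEvent:
    """One restart event; the events table carries one row per event with
    exactly these fields (plus ``edge_flag`` marking starts on the flat
    shoulder between the outermost well and an exit)."""

    trajectory_id: int
    start_index: int
    start_well: int
    m: int
    exit_side: str
    t_fpt: float
    edge_flag: bool = False


@dataclass
class FPTDistribution:
    """Normalized first-passage-time density on logarithmic bins.

    ``density`` integrates to 1 over the binned range; ``counts`` keeps the
    raw per-bin event counts for Poisson weighting; ``ci_low``/``ci_high``
    hold the bootstrap envelope when attached.  ``frame_interval`` (when
    known) lets fits exclude the first two frames of time resolution.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_events: int
    m: int | None = None
    label: str = ""
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    ci_level: float | None = None
    frame_interval: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def log_halfwidth(self) -> np.ndarray:
        """Per-bin symmetric error of ln(density): half the log-space
        bootstrap envelope where available and positive, else the Poisson
        approximation 1/sqrt(count).  Zero-count bins get +inf."""
        out = np.full(len(self.density), np.inf)
        occ = self.counts > 0
        out[occ] = 1.0 / np.sqrt(self.counts[occ])
        if self.ci_low is not None and self.ci_high is not None:
            ok = occ & (self.ci_low > 0) & (self.ci_high > 0)
            out[ok] = 0.5 * (np.log(self.ci_high[ok]) - np.log(self.ci_low[ok]))
            out[ok] = np.maximum(out[ok], 1e-12)
        return out

    def plot(self, ax=None, loglog: bool = True, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        occ = self.density > 0
        x, y = self.bin_centers[occ], self.density[occ]
        if self.ci_low is not None:
            yerr = np.vstack([np.maximum(y - self.ci_low[occ], 0),
                              np.maximum(self.ci_high[occ] - y, 0)])
            ax.errorbar(x, y, yerr=yerr, fmt="o", ms=3, **kwargs)
        else:
            ax.plot(x, y, "o", ms=3, **kwargs)
        if loglog:
            ax.set_xscale("log")
            ax.set_yscale("log")
        ax.set_xlabel(r"$t_{\mathrm{FPT}}$ [s]")
        ax.set_ylabel(r"$P(t_{\mathrm{FPT}})$ [1/s]")
        return ax


def extract_fpt_events(traj: Trajectory, landscape: PotentialLandscape
                       ) -> pd.DataFrame:
    """Restart-rule events for one trajectory.

    The exit frame is the first recorded frame at or beyond an exit; every
    earlier frame i yields one event with ``t_fpt = t_exit - t_i``.  A
    trajectory that never exits yields an empty table.
    """
    lo, hi = landscape.exits
    x = traj.positions
    if traj.n_frames < 2:
        raise ValueError("trajectory needs at least 2 frames")
    out = (x <= lo) | (x >= hi)
    if not out.any():
        return pd.DataFrame(columns=EVENT_COLUMNS)
    k = int(np.argmax(out))
    side = "left" if x[k] <= lo else "right"
    xi = x[:k]
    region = landscape.well_region(xi).astype(int)
    n_wells = landscape.n_wells
    if n_wells == 0:
        m = np.zeros(k, dtype=int)
        edge = np.zeros(k, dtype=bool)
    else:
        m = region if side == "left" else n_wells - 1 - region
        centers = np.array([w.center for w in landscape.wells])
        widths = np.array([w.width for w in landscape.wells])
        edge = ((xi < centers[0] - widths[0]) |
                (xi > centers[-1] + widths[-1]))
    return pd.DataFrame({
        "trajectory_id": np.full(k, traj.trajectory_id, dtype=np.int64),
        "start_index": np.arange(k, dtype=np.int64),
        "start_well": region if n_wells else np.zeros(k, dtype=int),
        "m": m,
        "exit_side": side,
        "t_fpt": (k - np.arange(k)) * traj.frame_interval,
        "edge_flag": edge,
    })


def extract_fpt_events_ensemble(trajectories: list[Trajectory],
                                landscape: PotentialLandscape
                                ) -> tuple[pd.DataFrame, dict]:
    """Pool restart events over an ensemble.

    Returns the events table and a summary dict counting exiting and
    non-exiting (silently skipped, but reported) trajectories.
    """
    lo, hi = landscape.exits
    n_wells = landscape.n_wells
    if n_wells:
        centers = np.array([w.center for w in landscape.wells])
        widths = np.array([w.width for w in landscape.wells])
    tid_p, idx_p, well_p, m_p, side_p, t_p, edge_p = [], [], [], [], [], [], []
    n_exited = 0
    for traj in trajectories:
        x = traj.positions
        out = (x <= lo) | (x >= hi)
        if not out.any():
            continue
        n_exited += 1
        k = int(np.argmax(out))
        left = bool(x[k] <= lo)
        xi = x[:k]
        if n_wells:
            region = landscape.well_region(xi).astype(np.int16)
            m = region if left else n_wells - 1 - region
            edge = ((xi < centers[0] - widths[0]) |
                    (xi > centers[-1] + widths[-1]))
        else:
            region = np.zeros(k, dtype=np.int16)
            m = region
            edge = np.zeros(k, dtype=bool)
        tid_p.append(np.full(k, traj.trajectory_id, dtype=np.int32))
        idx_p.append(np.arange(k, dtype=np.int32))
        well_p.append(region)
        m_p.append(m.astype(np.int16))
        side_p.append(np.zeros(k, dtype=bool) if left
                      else np.ones(k, dtype=bool))
        t_p.append((k - np.arange(k)) * traj.frame_interval)
        edge_p.append(edge)
    if tid_p:
        side_codes = np.concatenate(side_p)
        events = pd.DataFrame({
            "trajectory_id": np.concatenate(tid_p),
            "start_index": np.concatenate(idx_p),
            "start_well": np.concatenate(well_p),
            "m": np.concatenate(m_p),
            "exit_side": pd.Categorical.from_codes(
                side_codes.astype(np.int8), categories=["left", "right"]),
            "t_fpt": np.concatenate(t_p),
            "edge_flag": np.concatenate(edge_p),
        })
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    if trajectories:
        events.attrs["frame_interval"] = trajectories[0].frame_interval
    summary = {"n_trajectories": len(trajectories),
               "n_exited": n_exited,
               "n_not_exited": len(trajectories) - n_exited,
               "n_events": len(events),
               "n_edge_flagged": int(events["edge_flag"].sum())
               if len(events) else 0}
    return events, summary


def select_events(events: pd.DataFrame, m: int, sides: str = "both"
                  ) -> pd.DataFrame:
    """Events of one m-class; ``sides`` is 'left', 'right' or 'both'
    (combining exits toward either reservoir into one distribution)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if sides not in ("left", "right", "both"):
        raise ValueError("sides must be 'left', 'right' or 'both'")
    sel = events["m"] == m
    if sides != "both":
        sel &= events["exit_side"] == sides
    out = events.loc[sel]
    out.attrs = dict(events.attrs)
    return out


def events_from_samples(samples, frame_interval: float | None = None
                        ) -> pd.DataFrame:
    """Wrap raw FPT samples (e.g. from jump chains or trace analysis) in the
    events-table schema so the distribution builder accepts them; all samples
    share one trajectory_id unless an id array is given."""
    samples = np.asarray(samples, dtype=float)
    return pd.DataFrame({
        "trajectory_id": np.zeros(samples.size, dtype=np.int64),
        "start_index": np.arange(samples.size, dtype=np.int64),
        "start_well": 0, "m": -1, "exit_side": "none",
        "t_fpt": samples, "edge_flag": False,
    })


def _log_edges(t_min: float, t_max: float, bins_per_decade: int) -> np.ndarray:
    if t_min <= 0:
        raise ValueError("t_min must be > 0")
    if t_max <= t_min:
        # all samples identical: a single bin around the common value
        return np.array([t_min * 0.999, t_min * 1.001])
    n = int(np.ceil(np.log10(t_max / t_min) * bins_per_decade))
    edges = t_min * (10.0 ** (np.arange(n + 1) / bins_per_decade))
    edges[-1] = max(edges[-1], t_max)
    return edges


def _density(samples: np.ndarray, edges: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    counts, _ = np.histogram(samples, bins=edges)
    widths = np.diff(edges)
    total = counts.sum()
    dens = counts / (total * widths) if total else np.zeros_like(widths)
    return dens, counts


def build_distribution(events, bins_per_decade: int = 8,
                       t_min: float | None = None, t_max: float | None = None,
                       min_events: int = 50, m: int | None = None,
                       label: str = "") -> FPTDistribution:
    """Log-binned normalized FPT density.

    ``events`` is an events table (column ``t_fpt``) or a plain array of
    samples.  Bins are half-open ``[l, r)`` (the last closed), logarithmically
    spaced with ``bins_per_decade`` bins per decade over ``[t_min, t_max]``
    (defaults: sample min/max).  Fewer than ``min_events`` samples raise.
    """
    frame_interval = None
    if isinstance(events, pd.DataFrame):
        samples = events["t_fpt"].to_numpy(dtype=float)
        if "frame_interval" in events.attrs:
            frame_interval = events.attrs["frame_interval"]
        if m is None and len(events) and (events["m"] >= 0).all() \
                and events["m"].nunique() == 1:
            m = int(events["m"].iloc[0])
    else:
        samples = np.asarray(events, dtype=float)
    if samples.size < min_events:
        raise ValueError(f"{samples.size} events < floor of {min_events}")
    if (samples <= 0).any():
        raise ValueError("t_fpt samples must be > 0")
    if frame_interval is None:
        # restart-rule times are integer frame multiples; recover the frame
        step = np.min(samples)
        if np.allclose(samples / step, np.round(samples / step), atol=1e-6):
            frame_interval = float(step)
    edges = _log_edges(t_min if t_min is not None else samples.min(),
                       t_max if t_max is not None else samples.max(),
                       bins_per_decade)
    dens, counts = _density(samples, edges)
    return FPTDistribution(bin_edges=edges, density=dens, counts=counts,
                           n_events=int(samples.size), m=m, label=label,
                           frame_interval=frame_interval,
                           meta={"bins_per_decade": bins_per_decade})


def bootstrap_ci(events: pd.DataFrame, n_boot: int = 500,
                 level: float = 0.68, seed: int = 0,
                 dist: FPTDistribution | None = None,
                 bins_per_decade: int = 8) -> FPTDistribution:
    """Block bootstrap over whole trajectories.

    Restart events within one trajectory are strongly dependent, so the
    resampling unit is the trajectory id, not the event.  Rebuilds the
    density ``n_boot`` times on the bins of ``dist`` (built from the events
    if not given) and attaches the percentile envelope at ``level``
    (default 0.68, i.e. one-sigma error bars).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ids = events["trajectory_id"].to_numpy()
    uniq, codes = np.unique(ids, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("bootstrap needs >= 2 trajectories to resample")
    if dist is None:
        dist = build_distribution(events, bins_per_decade=bins_per_decade)
    edges = dist.bin_edges
    t = events["t_fpt"].to_numpy(dtype=float)
    nb = len(edges) - 1
    # per-trajectory binned counts (n_traj x n_bins)
    bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, nb - 1)
    in_range = (t >= edges[0]) & (t <= edges[-1])
    mat = np.zeros((uniq.size, nb))
    np.add.at(mat, (codes[in_range], bin_idx[in_range]), 1.0)
    rng = np.random.default_rng(seed)
    widths = np.diff(edges)
    boots = np.empty((n_boot, nb))
    for b in range(n_boot):
        mult = np.bincount(rng.integers(0, uniq.size, size=uniq.size),
                           minlength=uniq.size).astype(float)
        counts = mult @ mat
        total = counts.sum()
        boots[b] = counts / (total * widths) if total else 0.0
    alpha = (1.0 - level) / 2.0
    ci_low = np.quantile(boots, alpha, axis=0)
    ci_high = np.quantile(boots, 1.0 - alpha, axis=0)
    return FPTDistribution(
        bin_edges=edges, density=dist.density, counts=dist.counts,
        n_events=dist.n_events, m=dist.m, label=dist.label,
        ci_low=ci_low, ci_high=ci_high, ci_level=level,
        frame_interval=dist.frame_interval,
        meta={**dist.meta, "n_boot": n_boot, "bootstrap_seed": seed})
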