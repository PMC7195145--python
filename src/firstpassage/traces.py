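"""First-passage analysis of 1D signal traces.

Two routes mirror the two molecular experiments:

* **two-extreme traces** (force spectroscopy): the initial state is a signal
  range on one side of a start threshold; the target is the opposite-extreme
  tail of the signal, placed by quantile (a small fraction ``epsilon`` of
  all points lies beyond it).  Every frame inside the start region is a
  restart origin; its FPT is the time to the first later frame beyond the
  target threshold.
* **stepwise traces** (nanopore hopper): the signal is segmented into
  discrete levels by threshold partition (with a minimum-dwell merge), each
  level maps to a foothold, and all transitions spanning the same number of
  intermediate footholds are pooled into one multi-hop FPT distribution.

Both routes yield plain FPT samples that feed the standard distribution
builder and regime fit unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SignalTrace

__all__ = [
    "StateWindows",
    "TraceFPTResult",
    "quantile_target",
    "trace_fpt",
    "segment_levels",
    "hop_fpt_events",
]


@dataclass
class StateWindows:
    """State definitions on a signal trace.

    For two-extreme FPTs set ``start_threshold``/``start_direction`` and
    ``target_threshold``/``target_direction``; for level segmentation set
    ``level_boundaries`` (ordered thresholds partitioning the signal) and
    ``min_dwell``.
    """

    start_threshold: float | None = None
    start_direction: str = "below"
    target_threshold: float | None = None
    target_direction: str = "above"
    epsilon: float = 0.005
    level_boundaries: np.ndarray | None = None
    min_dwell: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.05:
            raise ValueError("epsilon must be in (0, 0.05)")
        for d in (self.start_direction, self.target_direction):
            if d not in ("below", "above"):
                raise ValueError("directions must be 'below' or 'above'")
        if self.start_threshold is not None \
                and self.target_threshold is not None:
            if self.start_direction == self.target_direction:
                raise ValueError("start and target regions must lie on "
                                 "opposite sides")
            lo, hi = ((self.start_threshold, self.target_threshold)
                      if self.start_direction == "below"
                      else (self.target_threshold, self.start_threshold))
            if lo >= hi:
                raise ValueError("start and target regions overlap")
        if self.level_boundaries is not None:
            self.level_boundaries = np.asarray(self.level_boundaries,
                                               dtype=float)
            if (np.diff(self.level_boundaries) <= 0).any():
                raise ValueError("level_boundaries must increase strictly")


@dataclass
class TraceFPTResult:
    """FPT samples from a trace analysis, with censoring bookkeeping.

    ``block_ids`` groups samples into approximately independent blocks
    (time blocks for restart origins, cycles for hopper events) used as the
    resampling unit of the block bootstrap.
    """

    samples: np.ndarray
    block_ids: np.ndarray
    n_origins: int
    n_censored: int
    frame_interval: float

    @property
    def n_events(self) -> int:
        return int(self.samples.size)

    def pseudo_events(self) -> pd.DataFrame:
        """Events-table view accepted by the distribution builder."""
        df = pd.DataFrame({
            "trajectory_id": self.block_ids.astype(np.int64),
            "start_index": np.arange(self.samples.size, dtype=np.int64),
            "start_well": 0, "m": -1, "exit_side": "none",
            "t_fpt": self.samples, "edge_flag": False,
        })
        df.attrs["frame_interval"] = self.frame_interval
        return df


def quantile_target(trace: SignalTrace, side: str = "high",
                    epsilon: float = 0.005) -> float:
    """Opposite-extreme target threshold by empirical quantile.

    ``side='high'`` returns the (1 - epsilon) quantile (at most a fraction
    epsilon of points lies above), ``side='low'`` the epsilon quantile;
    linear interpolation between order statistics.
    """
    if trace.values.size == 0:
        raise ValueError("empty trace")
    if not 0 < epsilon < 0.05:
        raise ValueError("epsilon must be in (0, 0.05)")
    if np.ptp(trace.values) == 0:
        raise ValueError("constant trace: quantile target is degenerate")
    if side not in ("high", "low"):
        raise ValueError("side must be 'high' or 'low'")
    q = 1.0 - epsilon if side == "high" else epsilon
    return float(np.quantile(trace.values, q))


def _region_mask(values: np.ndarray, threshold: float, direction: str
                 ) -> np.ndarray:
    return values < threshold if direction == "below" else values > threshold


def trace_fpt(trace: SignalTrace, windows: StateWindows,
              n_blocks: int = 50) -> TraceFPTResult:
    """Restart-rule FPTs from the start region to the target region.

    Every frame in the start region is an origin; its FPT is the time to
    the first strictly later frame in the target region.  Origins with no
    later target crossing are right-censored and only counted.
    """
    if windows.start_threshold is None or windows.target_threshold is None:
        raise ValueError("start and target thresholds must be set")
    v = trace.values
    start = _region_mask(v, windows.start_threshold, windows.start_direction)
    target = _region_mask(v, windows.target_threshold,
                          windows.target_direction)
    if not start.any() or not target.any():
        raise ValueError("no frames in the start or target region")
    origins = np.flatnonzero(start)
    target_idx = np.flatnonzero(target)
    pos = np.searchsorted(target_idx, origins + 1)
    completed = pos < target_idx.size
    fpt = (target_idx[pos[completed]] - origins[completed]) \
        * trace.frame_interval
    block_len = max(len(v) // n_blocks, 1)
    blocks = origins[completed] // block_len
    return TraceFPTResult(samples=fpt.astype(float),
                          block_ids=blocks,
                          n_origins=int(origins.size),
                          n_censored=int(origins.size - completed.sum()),
                          frame_interval=trace.frame_interval)


def segment_levels(trace: SignalTrace, windows: StateWindows
                   ) -> tuple[pd.DataFrame, float]:
    """Threshold-partition level assignment with a minimum-dwell merge.

    Per-frame levels are ``searchsorted(level_boundaries, value)``; runs
    shorter than ``min_dwell`` are merged into the longer neighbouring run
    (repeatedly, shortest first).  Returns the ordered segment table
    ``(level, entry_t, dwell)`` and the fraction of frames reassigned by
    the merge (a segmentation quality metric).
    """
    if windows.level_boundaries is None:
        raise ValueError("level_boundaries must be set for segmentation")
    raw = np.searchsorted(windows.level_boundaries, trace.values)
    min_frames = max(int(round(windows.min_dwell / trace.frame_interval)), 1)
    levels = raw.copy()

    def rle(a):
        change = np.flatnonzero(np.diff(a) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [a.size]))
        return starts, ends, a[starts]

    starts, ends, vals = rle(levels)
    lengths = ends - starts
    # iteratively absorb sub-dwell runs into the longer neighbour
    while len(starts) > 1 and lengths.min() < min_frames:
        i = int(np.argmin(lengths))
        left_len = lengths[i - 1] if i > 0 else -1
        right_len = lengths[i + 1] if i < len(starts) - 1 else -1
        j = i - 1 if left_len >= right_len else i + 1
        levels[starts[i]:ends[i]] = vals[j]
        starts, ends, vals = rle(levels)
        lengths = ends - starts
    quality = float(np.mean(levels != raw))
    segments = pd.DataFrame({
        "level": vals.astype(int),
        "entry_t": starts * trace.frame_interval,
        "dwell": lengths * trace.frame_interval,
    })
    segments.attrs["frame_interval"] = trace.frame_interval
    return segments, quality


def hop_fpt_events(segments: pd.DataFrame, m: int,
                   cycle_breaks=None, descending_levels: bool = False
                   ) -> TraceFPTResult:
    """Pooled multi-hop FPTs: for every segment entry into foothold ``s``,
    the time until the trace first reaches foothold ``s + m + 1`` (crossing
    m intermediate footholds).  All foothold pairs with that separation are
    pooled, as all positions are treated as equivalent.

    ``descending_levels=True`` maps signal levels to footholds in reverse
    (a hopper whose current drops as the cargo advances).  Pairs interrupted
    by a cycle break (a new cargo on the track) or by the end of the trace
    are censored and counted, never emitted.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    levels = segments["level"].to_numpy()
    entry = segments["entry_t"].to_numpy(dtype=float)
    feet = (levels.max() - levels) if descending_levels else levels
    breaks = np.asarray(sorted(cycle_breaks), dtype=float) \
        if cycle_breaks is not None else np.empty(0)
    frame_interval = segments.attrs.get("frame_interval", 0.0)
    samples, blocks = [], []
    n_origins = n_censored = 0
    max_foot = feet.max() if len(feet) else 0
    for i in range(len(feet)):
        targetf = feet[i] + m + 1
        if targetf > max_foot:
            continue  # can never complete: not an eligible origin
        n_origins += 1
        cyc = int(np.searchsorted(breaks, entry[i], side="right"))
        t_break = breaks[cyc] if cyc < breaks.size else np.inf
        done = False
        for j in range(i + 1, len(feet)):
            if entry[j] >= t_break:
                break
            if feet[j] >= targetf:
                samples.append(entry[j] - entry[i])
                blocks.append(cyc)
                done = True
                break
        if not done:
            n_censored += 1
    return TraceFPTResult(samples=np.asarray(samples, dtype=float),
                          block_ids=np.asarray(blocks, dtype=np.int64),
                          n_origins=n_origins, n_censored=n_censored,
                          frame_interval=frame_interval)
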