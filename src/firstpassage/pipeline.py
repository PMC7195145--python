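"""High-level analyses: simulation -> FPT extraction -> regime fitting.

These functions compose the package end to end for the packaged study
presets and return plain dicts of results (plus the fitted objects), ready
for JSON serialization by the CLI.  Every randomized stage derives its seed
from the one passed in, so a run is reproducible from ``(preset, seed)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import presets as _presets
from .fpt import (bootstrap_ci, build_distribution,
                  extract_fpt_events_ensemble, select_events)
from .landscapes import (OccupancyHistogram, boltzmann_invert,
                         detect_wells_and_boundaries)
from .regime import (DepthScaling, ShortTimePowerLaw, ShortTimePowerLawResults,
                     bootstrap_slope_se, fit_loglog_slope)
from .traces import hop_fpt_events, quantile_target, segment_levels, trace_fpt
from .traces import StateWindows

__all__ = [
    "colloid_events",
    "colloid_fig1_analysis",
    "depth_sweep_analysis",
    "invert_occupancy_analysis",
    "hairpin_analysis",
    "hopper_analysis",
]


def _subseed(seed: int, k: int) -> int:
    return int((seed * 1000 + k) % (2 ** 31 - 1))


def _fit_class(events: pd.DataFrame, m: int, seed: int, n_boot: int = 200
               ) -> ShortTimePowerLawResults:
    sel = select_events(events, m, "both")
    dist = bootstrap_ci(sel, n_boot=max(n_boot, 100), seed=_subseed(seed, 7))
    # restart events are dense, so the visibility floor is tied to the
    # total count: it keeps the window out of the sparse deviation flank
    fit = ShortTimePowerLaw(dist, min_count_frac=1e-4).fit()
    bootstrap_slope_se(sel, fit, n_boot=max(n_boot // 2, 100),
                       seed=_subseed(seed, 8))
    fit.regime_length()
    return fit


def colloid_events(preset, seed: int, n_trajectories: int | None = None,
                   depth: float | None = None, chunk: int = 500,
                   keep_m: int | None = None):
    """Simulate a colloid preset in memory-bounded chunks and pool the
    restart events; returns (events, landscape, summary)."""
    ls = preset.landscape(depth)
    n_total = n_trajectories or preset.n_trajectories
    parts = []
    summary = {"n_trajectories": 0, "n_exited": 0, "n_not_exited": 0,
               "n_events": 0, "n_edge_flagged": 0}
    offset = 0
    k = 0
    while summary["n_trajectories"] < n_total:
        n = min(chunk, n_total - summary["n_trajectories"])
        trajs = preset.simulate(_subseed(seed, k), n_trajectories=n,
                                depth=depth)
        k += 1
        ev, s = extract_fpt_events_ensemble(trajs, ls)
        del trajs
        ev["trajectory_id"] = ev["trajectory_id"] + offset
        offset += n
        if keep_m is not None:
            ev = select_events(ev, keep_m, "both")
        parts.append(ev)
        for key in summary:
            summary[key] += s.get(key, 0)
    events = pd.concat(parts, ignore_index=True)
    events.attrs["frame_interval"] = preset.frame_interval
    summary["n_events"] = int(sum(len(p) for p in parts))
    return events, ls, summary


def colloid_fig1_analysis(seed: int, n_trajectories: int | None = None,
                          n_boot: int = 200, m_classes=(0, 1, 2, 3)) -> dict:
    """Closed loop on the four-well channel: per-m-class short-time fits."""
    preset = _presets.COLLOID_FIG1
    events, ls, summary = colloid_events(preset, seed, n_trajectories)
    fits = {m: _fit_class(events, m, seed, n_boot) for m in m_classes}
    return {
        "preset": preset.name,
        "seed": seed,
        "summary": summary,
        "fits": {m: f.to_dict() for m, f in fits.items()},
        "_fit_objects": fits,
        "_events": events,
        "_landscape": ls,
    }


def invert_occupancy_analysis(seed: int, n_trajectories: int = 300,
                              bin_width: float = 0.04) -> dict:
    """Occupancy -> potential round trip on the four-well preset.

    Pools all recorded positions of a fig1-preset ensemble, Boltzmann-inverts
    the histogram and detects wells; reports the recovered mean well depth
    against the generating depth.
    """
    preset = _presets.COLLOID_FIG1
    ls = preset.landscape()
    trajs = preset.simulate(_subseed(seed, 3), n_trajectories=n_trajectories)
    pos = np.concatenate([t.positions[:-1] for t in trajs])
    del trajs
    lo, hi = ls.exits
    pos = pos[(pos > lo) & (pos < hi)]
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist = OccupancyHistogram.from_positions(pos, bins=edges)
    inverted = boltzmann_invert(hist)
    detected = detect_wells_and_boundaries(inverted)
    depths = [w.depth for w in detected.wells]
    return {
        "preset": preset.name,
        "n_positions": int(pos.size),
        "generating_depth": preset.depth,
        "n_wells_detected": detected.n_wells,
        "well_depths": depths,
        "mean_depth": float(np.mean(depths)) if depths else np.nan,
        "_landscape": detected,
    }


def depth_sweep_analysis(seed: int, depths=(2.0, 3.0, 4.0, 5.0),
                         n_per_depth: int | None = None, m: int = 2,
                         n_boot: int = 200,
                         holdout_depth: float | None = 3.0) -> dict:
    """m = 2 short-time fits and regime lengths across a well-depth sweep.

    Fits the exponential depth law ``ln dt = dU + ln a_m`` on the measured
    regime lengths; ``holdout_depth`` (when given) is excluded from the
    calibration and its depth re-predicted from its own regime length as a
    parameter-recovery check.
    """
    per_depth = {}
    points = []
    for k, depth in enumerate(depths):
        preset = _presets.COLLOID_DEPTH_SWEEP[depth]
        events, ls, summary = colloid_events(
            preset, _subseed(seed, 10 + k), n_trajectories=n_per_depth,
            keep_m=m, chunk=250)
        fit = _fit_class(events, m, _subseed(seed, 20 + k), n_boot)
        per_depth[depth] = {"fit": fit.to_dict(), "summary": summary,
                            "n_events": int(len(events))}
        if not fit.delta_t_censored:
            points.append((depth, fit.delta_t, m))
        del events
    calib_points = [p for p in points
                    if holdout_depth is None or p[0] != holdout_depth]
    scaling = DepthScaling(calib_points).fit()
    out = {
        "per_depth": per_depth,
        "depth_law": {
            "intercepts": scaling.intercepts,
            "free_slopes": scaling.free_slopes,
            "n_points": scaling.n_points,
        },
        "slopes": {d: per_depth[d]["fit"]["slope"] for d in per_depth},
        "_scaling": scaling,
        "_points": points,
    }
    if holdout_depth is not None:
        held = [p for p in points if p[0] == holdout_depth]
        if held and m in scaling.intercepts:
            out["holdout"] = {
                "true_depth": holdout_depth,
                "predicted_depth": scaling.predict_depth(held[0][1], m),
            }
    return out


def hairpin_analysis(preset, seed: int, total_time: float | None = None,
                     n_boot: int = 200, t_floor: float = 0.003) -> dict:
    """Two-extreme trace path: quantile target, restart FPTs, regime fit.

    The folding direction is analysed: origins in the low-force (unfolded)
    start region, target at the (1 - epsilon) opposite-extreme quantile.
    """
    trace = preset.trace(_subseed(seed, 30), total_time=total_time)
    target = quantile_target(trace, side="high", epsilon=preset.epsilon)
    windows = StateWindows(start_threshold=preset.start_threshold,
                           start_direction="below",
                           target_threshold=target,
                           target_direction="above",
                           epsilon=preset.epsilon)
    res = trace_fpt(trace, windows)
    dist = build_distribution(res.pseudo_events(), min_events=50)
    # exclude the sub-noise-excursion region: below a few noise correlation
    # times a "passage" is an artefact of the fluctuating signal, the trace
    # analogue of the colloid's direct-transit deviations
    fit = ShortTimePowerLaw(dist, t_floor=t_floor).fit()
    bootstrap_slope_se(res.pseudo_events(), fit,
                       n_boot=max(n_boot // 2, 100), seed=_subseed(seed, 31))
    fit.regime_length()
    return {
        "preset": preset.name,
        "n_intermediates_true": preset.n_intermediates,
        "target_threshold": float(target),
        "start_threshold": float(preset.start_threshold),
        "n_origins": res.n_origins,
        "n_censored": res.n_censored,
        "fit": fit.to_dict(),
        "_fit_object": fit,
        "_trace": trace,
    }


def hopper_analysis(seed: int, n_cycles: int | None = None,
                    m_values=(1, 2), n_boot: int = 200) -> dict:
    """Stepwise-trace path: level segmentation, pooled multi-hop FPTs,
    regime fits for the requested m values."""
    preset = _presets.HOPPER_FIG3B
    trace = preset.trace(_subseed(seed, 40), n_cycles=n_cycles)
    level_edges = 0.5 * (np.asarray(preset.level_means)[:-1]
                         + np.asarray(preset.level_means)[1:])
    # steps are 8 sigma apart, so no dwell merge is needed; merging would
    # delete genuine fast dwell pairs and deform the short-time density
    windows = StateWindows(level_boundaries=np.sort(level_edges),
                           min_dwell=preset.frame_interval)
    segments, quality = segment_levels(trace, windows)
    # current drops as the cargo advances: map levels back to footholds
    descending = np.all(np.diff(preset.level_means) < 0)
    out = {"preset": preset.name, "segment_quality": quality,
           "n_segments": int(len(segments)), "fits": {}, "_fit_objects": {}}
    for m in m_values:
        res = hop_fpt_events(segments, m, cycle_breaks=trace.meta.get(
            "cycle_starts"), descending_levels=descending)
        dist = build_distribution(res.pseudo_events(), min_events=50)
        fit = fit_loglog_slope(dist)
        bootstrap_slope_se(res.pseudo_events(), fit,
                           n_boot=max(n_boot // 2, 100),
                           seed=_subseed(seed, 41 + m))
        fit.regime_length()
        out["fits"][m] = {**fit.to_dict(), "n_events": int(res.n_events),
                          "n_censored": int(res.n_censored)}
        out["_fit_objects"][m] = fit
    return out
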