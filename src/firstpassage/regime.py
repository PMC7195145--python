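"""Short-time power-law regime of first-passage-time distributions.

For passage across ``m`` intermediate states the FPT density behaves as
``ln P(t) ~ m ln t + C`` at short times, so the t -> 0 log-log slope of the
pre-peak regime counts the intermediates directly.  The length of that
regime, ``delta_t``, grows as ``exp(dU/kBT)`` with the well depth ``dU``,
which turns a regime-length measurement into a depth estimate once the
per-m prefactor is calibrated.

Two model classes implement this, statsmodels-style:

* :class:`ShortTimePowerLaw` — weighted fit of
  ``ln density = C + B ln t + c t`` over the pre-peak window of an
  :class:`~firstpassage.fpt.FPTDistribution`.  The exponential-cutoff term
  ``c t`` absorbs the leading departure from the pure power law (for a sum
  of exponential stages it is the exact leading correction), so the
  reported ``slope`` B estimates the short-time exponent without the
  downward bias a plain straight line picks up as the window nears the
  distribution's peak.  ``fit()`` returns
  :class:`ShortTimePowerLawResults` with the slope, its standard error,
  the chosen window, the inferred intermediate count and the regime
  length.
* :class:`DepthScaling` — per-m calibration of ``ln delta_t = dU + ln a_m``
  (unit slope fixed, free slope kept as a diagnostic) and the inverse map
  from a measured regime length to a depth in kBT.

Functional wrappers (:func:`fit_loglog_slope`, :func:`detect_regime_length`,
:func:`infer_intermediates`, :func:`calibrate_depth`,
:func:`depth_from_regime`) expose the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .fpt import FPTDistribution, build_distribution

__all__ = [
    "ShortTimePowerLaw", "ShortTimePowerLawResults",
    "DepthScaling", "DepthScalingResults",
    "NoShortTimeRegimeError",
    "fit_loglog_slope", "detect_regime_length", "infer_intermediates",
    "calibrate_depth", "depth_from_regime", "bootstrap_slope_se",
]

#: |slope - round(slope)| and slope SE must both be below this for the
#: integer interpretation to be flagged as unambiguous.
INTEGER_TOLERANCE = 0.25


class NoShortTimeRegimeError(ValueError):
    """Raised when the distribution has no resolvable pre-peak regime."""


@dataclass
class ShortTimePowerLawResults:
    """Fitted short-time regime: ln(density) = intercept + slope*ln(t) + c*t.

    ``slope`` is the t -> 0 log-log exponent (B - A - 1 in the discrete
    network picture); ``cutoff_coeff`` is the fitted coefficient of the
    exponential-cutoff correction (0 for a pure power law)."""

    slope: float
    slope_se: float
    intercept: float
    cutoff_coeff: float
    line_slope: float
    line_intercept: float
    window: tuple[float, float]
    window_bins: tuple[int, int]
    rsquared: float
    n_bins: int
    homogeneous: bool
    dist: FPTDistribution = field(repr=False)
    model: "ShortTimePowerLaw" = field(repr=False)

    # regime length (filled by regime_length / detect_regime_length)
    delta_t: float | None = None
    delta_t_censored: bool | None = None
    t_deviation: float | None = None

    @property
    def inferred_m(self) -> int:
        return int(round(max(self.slope, 0.0)))

    @property
    def integer_flag(self) -> bool:
        return (abs(self.slope - self.inferred_m) <= INTEGER_TOLERANCE
                and self.slope_se <= INTEGER_TOLERANCE)

    def powerlaw(self, t) -> np.ndarray:
        """The pure power-law component A t^B (the fitted short-time
        asymptote, without the cutoff correction)."""
        return np.exp(self.intercept + self.slope * np.log(np.asarray(t)))

    def fitted_line(self, t) -> np.ndarray:
        """The plain straight-line fit over the window on log-log axes —
        the line one would draw through the linear regime.  The regime
        length is measured against this line."""
        return np.exp(self.line_intercept
                      + self.line_slope * np.log(np.asarray(t)))

    def predict(self, t) -> np.ndarray:
        """The full fitted density curve A t^B exp(c t)."""
        t = np.asarray(t)
        return np.exp(self.intercept + self.slope * np.log(t)
                      + self.cutoff_coeff * t)

    def regime_length(self, deviation_k: float = 2.0) -> float:
        """Length delta_t of the power-law regime.

        The deviation time ``t_dev`` is the first time past the window start
        at which the fitted density falls below the straight line drawn
        through the linear regime by more than ``deviation_k`` times the
        typical (median over window bins) error half-width of ln(density).
        Measuring the deviation on the fitted curve rather than on raw bins
        removes bin-level shot noise from the regime length;
        ``delta_t = t_dev - t_start``.  With no deviation before the last
        occupied bin, delta_t is right-censored there (flagged).
        """
        d = self.dist
        centers = d.bin_centers
        hw = d.log_halfwidth()
        occ = np.flatnonzero(d.density > 0)
        t_start = self.window[0]
        t_max = float(centers[occ[-1]])
        lo_bin, hi_bin = self.window_bins
        win_bins = occ[(occ >= lo_bin) & (occ <= hi_bin)]
        h_typ = float(np.median(hw[win_bins]))
        thresh = deviation_k * h_typ

        def gap(t):
            return (np.log(self.predict(t)) - np.log(self.fitted_line(t))
                    + thresh)

        t_dev = None
        if self.cutoff_coeff < 0 and t_max > t_start:
            grid = np.geomspace(t_start, t_max, 256)
            g = gap(grid)
            # the gap dips at both window edges; only the late, persistent
            # departure past its maximum marks the end of the regime
            j0 = int(np.argmax(g))
            below = np.flatnonzero(g[j0:] < 0)
            if below.size:
                j = j0 + below[0]
                from scipy.optimize import brentq
                t_dev = float(brentq(gap, grid[max(j - 1, 0)], grid[j])) \
                    if j > j0 else float(grid[j])
        if t_dev is None:
            self.delta_t = float(t_max - t_start)
            self.delta_t_censored = True
            self.t_deviation = t_max
        else:
            self.delta_t = float(t_dev - t_start)
            self.delta_t_censored = False
            self.t_deviation = t_dev
        return self.delta_t

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "slope_se": self.slope_se,
            "intercept": self.intercept, "cutoff_coeff": self.cutoff_coeff,
            "window": list(self.window), "window_bins": list(self.window_bins),
            "r_squared": self.rsquared, "n_bins": self.n_bins,
            "homogeneous": self.homogeneous,
            "inferred_m": self.inferred_m, "integer_flag": self.integer_flag,
            "delta_t": self.delta_t, "delta_t_censored": self.delta_t_censored,
            "t_deviation": self.t_deviation,
        }

    def summary(self) -> str:
        lines = [
            "Short-time power-law regime fit",
            "=" * 46,
            f"slope (B - A - 1)     {self.slope:10.4f} +/- {self.slope_se:.4f}",
            f"intercept C           {self.intercept:10.4f}",
            f"cutoff coefficient    {self.cutoff_coeff:10.4f} 1/s",
            f"window [s]            [{self.window[0]:.4g}, {self.window[1]:.4g}]",
            f"bins in fit           {self.n_bins:10d}",
            f"R^2                   {self.rsquared:10.4f}",
            f"consistent window     {str(self.homogeneous):>10s}",
            f"inferred m            {self.inferred_m:10d}"
            f"  (integer_flag={self.integer_flag})",
        ]
        if self.delta_t is not None:
            cens = " (right-censored)" if self.delta_t_censored else ""
            lines.append(f"regime length delta_t {self.delta_t:10.4g} s{cens}")
        return "\n".join(lines)

    def plot(self, ax=None):
        ax = self.dist.plot(ax=ax, loglog=True)
        t = np.geomspace(*self.window, 50)
        ax.plot(t, self.powerlaw(t), "k--", lw=1.5,
                label=f"slope {self.slope:.2f}")
        ax.legend()
        return ax


class ShortTimePowerLaw:
    """Weighted least-squares model of the pre-peak short-time regime.

    The automatic window spans the occupied, populated (count >=
    ``min_count``) bins from the third occupied bin above
    ``resolution_frames`` frame intervals up to the bin before the
    distribution's mode.  Leading bins belonging to the very-short-time
    deviation region — direct, transit-limited passages whose log-log flank
    is far steeper than any state-counting exponent — are then trimmed
    iteratively: while the leading 3-bin chord slope exceeds the fitted
    exponent by more than ``flank_threshold``, the first bin is dropped and
    the model refit.  For monotone-decreasing densities (no pre-peak bins,
    the m = 0 case) the end bound is the bin holding the 75th percentile of
    the samples.  Weights are the symmetric log-space errors from the
    bootstrap envelope (Poisson fallback); the chi-square consistency of
    the final window is reported as ``homogeneous``.
    """

    def __init__(self, dist: FPTDistribution, min_bins: int = 4,
                 skip_occupied: int = 2, resolution_frames: int = 2,
                 min_count: int = 2, min_count_frac: float = 0.0,
                 flank_threshold: float = 1.5,
                 max_trim: int = 25, curvature: bool = True,
                 gof_p: float = 0.05, t_floor: float | None = None):
        self.dist = dist
        self.min_bins = min_bins
        self.skip_occupied = skip_occupied
        self.resolution_frames = resolution_frames
        self.t_floor = t_floor
        self.min_count = min_count
        self.min_count_frac = min_count_frac
        self.flank_threshold = flank_threshold
        self.max_trim = max_trim
        self.curvature = curvature
        self.gof_p = gof_p

    # -- internals ---------------------------------------------------------

    def _wls(self, bins):
        d = self.dist
        t = d.bin_centers[bins]
        lnt = np.log(t)
        lny = np.log(d.density[bins])
        sig = np.maximum(d.log_halfwidth()[bins], 1e-12)
        cols = [np.ones_like(lnt), lnt]
        # the cutoff term needs a few extra bins to be identifiable
        use_curv = self.curvature and len(bins) >= self.min_bins + 1
        if use_curv:
            cols.append(t)
        X = np.column_stack(cols)
        res = sm.WLS(lny, X, weights=1.0 / sig ** 2).fit()
        if use_curv and res.params[2] > 0:
            # the cutoff term models decay only; a positive coefficient is
            # an ill-conditioned artefact -> drop it and refit the line
            use_curv = False
            X = X[:, :2]
            res = sm.WLS(lny, X, weights=1.0 / sig ** 2).fit()
        chi2 = float(np.sum(((lny - res.fittedvalues) / sig) ** 2))
        dof = max(len(bins) - X.shape[1], 1)
        p = float(sps.chi2.sf(chi2, dof))
        return res, p, use_curv

    # -- fitting -----------------------------------------------------------

    def fit(self, window: str | tuple[float, float] = "auto"
            ) -> ShortTimePowerLawResults:
        d = self.dist
        centers = d.bin_centers
        occ = np.flatnonzero(d.density > 0)
        if len(occ) < self.min_bins:
            raise NoShortTimeRegimeError(
                f"only {len(occ)} occupied bins; need >= {self.min_bins}")

        if window != "auto":
            t1, t2 = window
            bins = occ[(centers[occ] >= t1) & (centers[occ] <= t2)]
            if len(bins) < self.min_bins:
                raise NoShortTimeRegimeError(
                    "fewer than min_bins occupied bins in explicit window")
            res, p, use_curv = self._wls(bins)
            return self._pack(res, bins, centers, use_curv,
                              homogeneous=p >= self.gof_p)

        low_cut = (self.resolution_frames * d.frame_interval
                   if d.frame_interval else 0.0)
        if self.t_floor is not None:
            low_cut = max(low_cut, self.t_floor)
        # visibility floor: absolute, plus a fixed fraction of the total
        # event count so the window start does not crawl into the sparse
        # deviation flank as statistics grow (scale-invariant windowing)
        floor = max(self.min_count,
                    self.min_count_frac * float(d.counts.sum()))
        eligible = occ[(centers[occ] > low_cut)
                       & (self.dist.counts[occ] >= floor)]
        if len(eligible) < self.min_bins + self.skip_occupied:
            raise NoShortTimeRegimeError(
                "too few occupied bins above the resolution cut")
        s0_pos = self.skip_occupied
        usable = eligible[s0_pos:]
        mode = occ[int(np.argmax(d.density[occ]))]
        pre = usable[usable < mode]
        if len(pre) < self.min_bins:
            # monotone-decreasing density: bound by the 75th-percentile bin
            csum = np.cumsum(d.counts)
            q_bin = int(np.searchsorted(csum, 0.75 * csum[-1]))
            pre = usable[usable <= q_bin]
        if len(pre) < self.min_bins:
            raise NoShortTimeRegimeError(
                "no resolvable short-time regime (mode at or below the "
                "window start)")

        # Reference exponent from the trailing half of the pre-peak bins:
        # that region is always past the very-short-time deviation flank,
        # so it anchors the flank trim without chasing the flank itself.
        tail = pre[max(len(pre) - max(self.min_bins + 1, len(pre) // 2), 0):]
        ref, _, _ = self._wls(tail)
        b_ref = float(ref.params[1])

        bins = pre
        res = p = use_curv = None
        for _ in range(self.max_trim):
            res, p, use_curv = self._wls(bins)
            if len(bins) <= self.min_bins:
                break
            lnt = np.log(centers[bins[:3]])
            lny = np.log(d.density[bins[:3]])
            lead_slope = (lny[2] - lny[0]) / (lnt[2] - lnt[0])
            if lead_slope - b_ref > self.flank_threshold:
                bins = bins[1:]
            else:
                break
        return self._pack(res, bins, centers, use_curv,
                          homogeneous=p >= self.gof_p)

    def _line_fit(self, bins):
        d = self.dist
        lnt = np.log(d.bin_centers[bins])
        lny = np.log(d.density[bins])
        sig = np.maximum(d.log_halfwidth()[bins], 1e-12)
        X = np.column_stack([np.ones_like(lnt), lnt])
        return sm.WLS(lny, X, weights=1.0 / sig ** 2).fit()

    def _pack(self, res, bins, centers, use_curv, homogeneous: bool
              ) -> ShortTimePowerLawResults:
        nparam = 3 if use_curv else 2
        rsq = float(res.rsquared) if res.nobs > nparam else 1.0
        if use_curv:
            line = self._line_fit(bins)
            line_params = (float(line.params[0]), float(line.params[1]))
        else:
            line_params = (float(res.params[0]), float(res.params[1]))
        return ShortTimePowerLawResults(
            slope=float(res.params[1]), slope_se=float(res.bse[1]),
            intercept=float(res.params[0]),
            cutoff_coeff=float(res.params[2]) if use_curv else 0.0,
            line_intercept=line_params[0], line_slope=line_params[1],
            window=(float(centers[bins[0]]), float(centers[bins[-1]])),
            window_bins=(int(bins[0]), int(bins[-1])),
            rsquared=rsq, n_bins=len(bins), homogeneous=homogeneous,
            dist=self.dist, model=self)


def bootstrap_slope_se(events: pd.DataFrame, fit: ShortTimePowerLawResults,
                       n_boot: int = 200, seed: int = 0) -> float:
    """Block-bootstrap standard error of the fitted slope.

    Trajectories (not events) are resampled with replacement, the density is
    rebuilt on the fitted distribution's bins and the model refit on the
    same window; the SD of the bootstrap slopes is returned and stored on
    the results object (it supersedes the WLS standard error, which
    understates the sampling variability of sparse log-binned counts).
    """
    d = fit.dist
    edges = d.bin_edges
    widths = np.diff(edges)
    nb = len(widths)
    t = events["t_fpt"].to_numpy(dtype=float)
    ids = events["trajectory_id"].to_numpy()
    uniq, codes = np.unique(ids, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("bootstrap needs >= 2 trajectories")
    bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, nb - 1)
    in_range = (t >= edges[0]) & (t <= edges[-1])
    mat = np.zeros((uniq.size, nb))
    np.add.at(mat, (codes[in_range], bin_idx[in_range]), 1.0)
    rng = np.random.default_rng(seed)
    lo_bin, hi_bin = fit.window_bins
    slopes = []
    for _ in range(n_boot):
        mult = np.bincount(rng.integers(0, uniq.size, size=uniq.size),
                           minlength=uniq.size).astype(float)
        counts = mult @ mat
        total = counts.sum()
        if total == 0:
            continue
        dens = counts / (total * widths)
        bd = FPTDistribution(bin_edges=edges, density=dens, counts=counts,
                             n_events=int(total), m=d.m,
                             frame_interval=d.frame_interval)
        bins = np.flatnonzero(dens > 0)
        bins = bins[(bins >= lo_bin) & (bins <= hi_bin)]
        if len(bins) < 3:
            continue
        model = ShortTimePowerLaw(bd, curvature=fit.model.curvature)
        res, _, _ = model._wls(bins)
        slopes.append(float(res.params[1]))
    if len(slopes) < n_boot // 2:
        raise RuntimeError("too many degenerate bootstrap replicates")
    se = float(np.std(slopes, ddof=1))
    fit.slope_se = max(fit.slope_se, se)
    return se


# ---------------------------------------------------------------------------
# depth calibration
# ---------------------------------------------------------------------------

@dataclass
class DepthScalingResults:
    """Per-m calibration of ln(delta_t) = dU/kBT + ln(a_m)."""

    intercepts: dict[int, float]           # ln a_m per m
    residuals: dict[int, np.ndarray]
    free_slopes: dict[int, tuple[float, float]]   # (slope, se) diagnostics
    n_points: dict[int, int]

    def predict_depth(self, delta_t: float, m: int) -> float:
        """Invert the unit-slope law: dU = ln(delta_t) - ln(a_m), in kBT."""
        if m not in self.intercepts:
            raise KeyError(f"no calibration for m={m}; have "
                           f"{sorted(self.intercepts)}")
        return float(np.log(delta_t) - self.intercepts[m])

    def summary(self) -> str:
        lines = ["Regime-length depth calibration: ln dt = dU/kBT + ln a_m",
                 "=" * 58]
        for m in sorted(self.intercepts):
            fs, fse = self.free_slopes.get(m, (np.nan, np.nan))
            lines.append(
                f"m={m}: ln a_m = {self.intercepts[m]:8.4f}  "
                f"(n={self.n_points[m]}, free slope {fs:.3f} +/- {fse:.3f}, "
                f"rms resid {np.sqrt(np.mean(self.residuals[m]**2)):.3f})")
        return "\n".join(lines)


class DepthScaling:
    """Calibrate the exponential depth law of the regime length.

    ``points`` is an iterable of ``(dU_kBT, delta_t_seconds, m)``.  The fit
    fixes the slope of ln(delta_t) versus dU/kBT at 1 (the exponential law)
    and estimates the per-m prefactor ``ln a_m``; an unconstrained per-m
    straight-line fit is kept as a diagnostic of the law itself.
    """

    def __init__(self, points):
        self.points = [(float(u), float(t), int(m)) for u, t, m in points]

    def fit(self) -> DepthScalingResults:
        by_m: dict[int, list[tuple[float, float]]] = {}
        for u, t, m in self.points:
            by_m.setdefault(m, []).append((u, t))
        intercepts, residuals, free, npts = {}, {}, {}, {}
        for m, pts in by_m.items():
            if len(pts) < 2:
                continue
            u = np.array([p[0] for p in pts])
            lndt = np.log([p[1] for p in pts])
            a = lndt - u
            intercepts[m] = float(a.mean())
            residuals[m] = a - a.mean()
            npts[m] = len(pts)
            ols = sm.OLS(lndt, sm.add_constant(u)).fit()
            free[m] = (float(ols.params[1]),
                       float(ols.bse[1]) if len(pts) > 2 else np.nan)
        if not intercepts:
            raise ValueError("need >= 2 (dU, delta_t) points for at least "
                             "one m")
        return DepthScalingResults(intercepts=intercepts, residuals=residuals,
                                   free_slopes=free, n_points=npts)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_loglog_slope(dist: FPTDistribution,
                     window_policy: str | tuple[float, float] = "auto"
                     ) -> ShortTimePowerLawResults:
    """Fit the short-time regime (see :class:`ShortTimePowerLaw`)."""
    return ShortTimePowerLaw(dist).fit(window=window_policy)


def detect_regime_length(dist: FPTDistribution,
                         fit: ShortTimePowerLawResults,
                         deviation_k: float = 2.0) -> float:
    """Length of the power-law regime (see
    :meth:`ShortTimePowerLawResults.regime_length`)."""
    if fit.dist is not dist:
        fit = ShortTimePowerLaw(dist).fit(window=fit.window)
    return fit.regime_length(deviation_k=deviation_k)


def infer_intermediates(fit: ShortTimePowerLawResults,
                        tolerance: float = INTEGER_TOLERANCE
                        ) -> tuple[int, bool]:
    """Nearest nonnegative integer to the slope, with a flag that is true
    only when the slope is unambiguously integer at the given tolerance."""
    m = int(round(max(fit.slope, 0.0)))
    flag = (abs(fit.slope - m) <= tolerance and fit.slope_se <= tolerance)
    return m, flag


def calibrate_depth(points) -> DepthScalingResults:
    """Fit the per-m exponential depth law (see :class:`DepthScaling`)."""
    return DepthScaling(points).fit()


def depth_from_regime(delta_t: float, m: int,
                      calibration: DepthScalingResults) -> float:
    """Well depth in kBT from a measured regime length."""
    return calibration.predict_depth(delta_t, m)
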