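"""1D potential-of-mean-force landscapes.

A landscape is a potential :math:`U(x)` (in units of ``kBT``) on a uniform
grid spanning a channel with absorbing exits at both ends.  Metastable wells
and the barriers (boundaries) between them partition the channel into start
regions for first-passage analysis; the *m*-class of a position counts the
intermediate wells that must be crossed to reach a chosen exit.

Potentials can be built synthetically (:func:`make_channel_landscape`) or
recovered from position occupancy by Boltzmann inversion,
``U(x) = -kBT ln P(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Well",
    "PotentialLandscape",
    "OccupancyHistogram",
    "make_channel_landscape",
    "marginalize_xy",
    "boltzmann_invert",
    "detect_wells_and_boundaries",
    "m_class",
]

#: Default topographic prominence (kBT) for a local minimum to count as a well.
DEFAULT_PROMINENCE = 0.5


@dataclass(frozen=True)
class Well:
    """A potential minimum: position of the center, escape-relevant depth
    (lower flanking barrier minus minimum, kBT) and full width at half depth."""

    center: float
    depth: float
    width: float


@dataclass
class PotentialLandscape:
    """Potential U(x) in kBT on a uniform grid with absorbing exits.

    ``U`` may contain NaN where occupancy was zero (inversion leaves such
    bins undefined rather than extrapolating).  ``wells`` and ``boundaries``
    are populated either analytically (synthetic landscapes) or by
    :func:`detect_wells_and_boundaries`.
    """

    x_grid: np.ndarray
    U: np.ndarray
    exits: tuple[float, float]
    wells: list[Well] = field(default_factory=list)
    boundaries: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = ""

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.x_grid.ndim != 1 or self.x_grid.shape != self.U.shape:
            raise ValueError("x_grid and U must be 1D arrays of equal length")
        if len(self.x_grid) >= 2:
            steps = np.diff(self.x_grid)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("x_grid must be uniformly spaced")
        lo, hi = self.exits
        if not lo < hi:
            raise ValueError("exits must satisfy left < right")

    @property
    def grid_step(self) -> float:
        return float(self.x_grid[1] - self.x_grid[0])

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def force(self) -> np.ndarray:
        """-dU/dx by centered finite differences (kBT per length unit)."""
        if np.isnan(self.U).any():
            raise ValueError("potential has undefined (NaN) grid points; "
                             "interpolate via detect_wells_and_boundaries first")
        return -np.gradient(self.U, self.x_grid)

    def contains(self, x: float) -> bool:
        lo, hi = self.exits
        return lo < x < hi

    def well_region(self, x: float | np.ndarray) -> np.ndarray:
        """Index of the well region containing x; regions are half-open
        ``[boundary, next boundary)``, delimited by the boundaries and the
        exits at the outside."""
        return np.searchsorted(self.boundaries, np.asarray(x, dtype=float),
                               side="right")

    def plot(self, ax=None):
        """Plot U(x) with well centers, boundaries and exits annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x_grid, self.U, "k-", lw=1.5)
        for w in self.wells:
            ax.axvline(w.center, color="C0", ls=":", lw=0.8)
        for b in self.boundaries:
            ax.axvline(b, color="0.5", ls="--", lw=0.8)
        for e in self.exits:
            ax.axvline(e, color="k", ls="-", lw=1.2)
        ax.set_xlabel("x")
        ax.set_ylabel("U(x) [kBT]")
        return ax


@dataclass
class OccupancyHistogram:
    """Binned counts of observed positions, 1D over x or 2D over (x, y).

    For 2D input ``bin_edges`` is a pair of edge arrays and ``counts`` has
    shape (n_x, n_y) with rows indexed by x.
    """

    bin_edges: np.ndarray | tuple[np.ndarray, np.ndarray]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def ndim(self) -> int:
        return self.counts.ndim

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges if self.ndim == 1 else self.bin_edges[0]
        edges = np.asarray(edges, dtype=float)
        return 0.5 * (edges[:-1] + edges[1:])

    @classmethod
    def from_positions(cls, x: np.ndarray, bins: int | np.ndarray,
                       range_: tuple[float, float] | None = None
                       ) -> "OccupancyHistogram":
        counts, edges = np.histogram(np.asarray(x, dtype=float), bins=bins,
                                     range=range_)
        return cls(bin_edges=edges, counts=counts)


def make_channel_landscape(n_wells: int, depth: float, channel_length: float,
                           well_width: float = 0.42, grid_step: float = 0.01,
                           exit_barrier_extra: float | None = None,
                           label: str = "") -> PotentialLandscape:
    """Synthetic channel potential: equally spaced Gaussian wells on a flat
    background, absorbing exits at 0 and ``channel_length``.

    Adjacent wells overlap, so the barrier between wells is a rounded
    saddle below the flat background (as for overlapping optical traps);
    the Gaussian amplitude is rescaled so that the realized
    escape-relevant well depth — lower flanking barrier minus minimum —
    equals ``depth`` exactly.  By default the background toward the exits
    is flat, so the outermost barriers (full trap amplitude) are higher
    than the inter-well saddles, as for traps placed inside a featureless
    channel.  ``exit_barrier_extra`` caps that asymmetry: ghost wells one
    spacing beyond each exit (the attraction of the reservoirs) are given
    the partial amplitude that makes the outermost barrier exceed the well
    depth by exactly that many kBT (0 recovers a fully periodic channel
    with absorption at barrier crests).

    Parameters
    ----------
    n_wells : number of wells (0 gives a flat channel).
    depth : escape-relevant well depth in kBT.
    channel_length : channel span in length units; wells are centred at
        ``(i + 1/2) * channel_length / n_wells``.
    well_width : Gaussian sigma of each well.
    grid_step : grid resolution.
    """
    if n_wells < 0:
        raise ValueError("n_wells must be >= 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    x = np.arange(0.0, channel_length + grid_step / 2, grid_step)
    U = np.zeros_like(x)
    centers = (np.arange(n_wells) + 0.5) * channel_length / max(n_wells, 1)
    if n_wells >= 2:
        spacing = centers[1] - centers[0]
        if well_width >= spacing:
            raise ValueError("well_width must be smaller than the well spacing")
    else:
        spacing = channel_length
    label = label or f"channel-{n_wells}w-{depth}kT"
    if n_wells == 0 or depth == 0:
        return PotentialLandscape(x_grid=x, U=np.zeros_like(x),
                                  exits=(0.0, float(channel_length)),
                                  label=label)

    def shape(ghost_amp: float) -> np.ndarray:
        Us = np.zeros_like(x)
        for c in centers:
            Us -= np.exp(-((x - c) ** 2) / (2.0 * well_width ** 2))
        for c in (centers[0] - spacing, centers[-1] + spacing):
            Us -= ghost_amp * np.exp(-((x - c) ** 2)
                                     / (2.0 * well_width ** 2))
        return Us - Us.min()

    def probe_metrics(ghost_amp: float):
        unit = PotentialLandscape(x_grid=x, U=shape(ghost_amp),
                                  exits=(0.0, float(channel_length)))
        det = detect_wells_and_boundaries(unit, prominence=1e-3)
        if det.n_wells != n_wells:
            raise ValueError(
                f"requested {n_wells} wells but construction yields "
                f"{det.n_wells} resolvable minima (wells overlap too "
                f"strongly)")
        shape_depth = min(w.depth for w in det.wells)
        k0 = int(np.searchsorted(x, det.wells[0].center))
        outer_barrier = det.U[:k0 + 1].max() - det.U[k0]
        return shape_depth, outer_barrier

    if exit_barrier_extra is None:
        g = 0.0
    else:
        # bisection on the ghost amplitude for the requested exit barrier
        target = exit_barrier_extra / depth  # in units of the well depth
        lo_g, hi_g = 0.0, 1.0
        for _ in range(40):
            g = 0.5 * (lo_g + hi_g)
            sd, ob = probe_metrics(g)
            if ob / sd - 1.0 > target:
                lo_g = g
            else:
                hi_g = g
    sd, _ = probe_metrics(g)
    U = shape(g) * (depth / sd)
    ls = PotentialLandscape(x_grid=x, U=U, exits=(0.0, float(channel_length)),
                            label=label)
    return detect_wells_and_boundaries(ls, prominence=min(DEFAULT_PROMINENCE,
                                                          depth / 2))


def marginalize_xy(hist2d: OccupancyHistogram) -> OccupancyHistogram:
    """Marginalize a 2D (x, y) occupancy histogram over y.

    Rows of ``counts`` index x; the result is the 1D occupancy over x with
    the total count preserved.
    """
    if hist2d.ndim != 2:
        raise ValueError("marginalize_xy expects a 2D histogram")
    if hist2d.total <= 0:
        raise ValueError("empty histogram")
    x_edges = np.asarray(hist2d.bin_edges[0], dtype=float)
    return OccupancyHistogram(bin_edges=x_edges, counts=hist2d.counts.sum(axis=1))


def boltzmann_invert(hist: OccupancyHistogram, kBT: float = 1.0
                     ) -> PotentialLandscape:
    """Recover the potential of mean force from occupancy: U = -kBT ln P(x).

    The result is shifted so the minimum over defined bins is 0.  Bins with
    zero count are left NaN (undefined) — occupancy that was never observed
    is not extrapolated.  Wells/boundaries are left unset; run
    :func:`detect_wells_and_boundaries` to populate them.
    """
    if hist.ndim != 1:
        raise ValueError("boltzmann_invert expects a 1D histogram; "
                         "marginalize 2D occupancy first")
    total = hist.total
    if total <= 0:
        raise ValueError("all-zero counts: nothing to invert")
    with np.errstate(divide="ignore"):
        U = -kBT * np.log(hist.counts / total)
    U[hist.counts == 0] = np.nan
    U -= np.nanmin(U)
    edges = np.asarray(hist.bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PotentialLandscape(x_grid=centers, U=U,
                              exits=(float(edges[0]), float(edges[-1])),
                              label="inverted")


def _fill_small_gaps(U: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linearly interpolate runs of <= max_gap consecutive NaNs; longer runs
    are an error (the potential is considered non-contiguous)."""
    U = U.copy()
    isnan = np.isnan(U)
    if not isnan.any():
        return U
    # Identify NaN runs.
    idx = np.flatnonzero(isnan)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if len(run) > max_gap or run[0] == 0 or run[-1] == len(U) - 1:
            raise ValueError(
                f"potential undefined over {len(run)} consecutive bins "
                f"(> {max_gap} or at the edge): non-contiguous landscape")
    good = ~isnan
    U[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), U[good])
    return U


def detect_wells_and_boundaries(landscape: PotentialLandscape,
                                prominence: float = DEFAULT_PROMINENCE
                                ) -> PotentialLandscape:
    """Locate wells (local minima of topographic prominence >= ``prominence``)
    and the boundaries (highest point of U between adjacent wells).

    Returns a new landscape with ``wells`` and ``boundaries`` populated.
    Each well's depth is the lower of its two flanking barrier heights minus
    U at the well center (the escape-relevant depth); for the outermost wells
    the exit-side barrier is the maximum of U between the center and the
    channel end.
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    U = _fill_small_gaps(landscape.U)
    x = landscape.x_grid
    minima, _ = find_peaks(-U, prominence=prominence)
    if len(minima) == 0:
        return PotentialLandscape(x_grid=x, U=U, exits=landscape.exits,
                                  wells=[], boundaries=np.empty(0),
                                  label=landscape.label)
    # Boundaries: argmax of U between each adjacent pair of wells.
    boundaries = []
    for a, b in zip(minima[:-1], minima[1:]):
        k = a + int(np.argmax(U[a:b + 1]))
        boundaries.append(x[k])
    # Barrier heights flanking each well (exit side uses the edge segment).
    wells = []
    seg_edges = [0, *[int(np.searchsorted(x, b)) for b in boundaries], len(x) - 1]
    for i, k in enumerate(minima):
        left_barrier = U[seg_edges[i]:k + 1].max()
        right_barrier = U[k:seg_edges[i + 1] + 1].max()
        depth = min(left_barrier, right_barrier) - U[k]
        # Full width at half depth around the minimum.
        half = U[k] + depth / 2.0
        lo = k
        while lo > 0 and U[lo] < half:
            lo -= 1
        hi = k
        while hi < len(U) - 1 and U[hi] < half:
            hi += 1
        wells.append(Well(center=float(x[k]), depth=float(depth),
                          width=float(x[hi] - x[lo])))
    return PotentialLandscape(x_grid=x, U=U, exits=landscape.exits,
                              wells=wells,
                              boundaries=np.asarray(boundaries, dtype=float),
                              label=landscape.label)


def m_class(start_x: float, exit_side: str,
            landscape: PotentialLandscape) -> int:
    """Minimum number of intermediate wells between the well region holding
    ``start_x`` and the chosen exit (0 if the start region is adjacent to it).

    Regions are delimited by the boundaries: a position between the exit and
    the outermost boundary belongs to the outermost well region.
    """
    if exit_side not in ("left", "right"):
        raise ValueError("exit_side must be 'left' or 'right'")
    if not landscape.contains(start_x):
        raise ValueError(f"start_x={start_x} outside the channel "
                         f"{landscape.exits}")
    if landscape.n_wells == 0:
        return 0
    region = int(landscape.well_region(start_x))
    return region if exit_side == "left" else landscape.n_wells - 1 - region
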