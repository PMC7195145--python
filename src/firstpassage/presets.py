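"""Named study presets.

Each preset packages the generating conditions for one synthetic system so
analyses and tests reference a name instead of loose numbers:

* ``colloid-fig1`` — four optical-trap wells of depth 3 kBT in a 4.8 µm
  channel, 60 Hz frames, trajectories released at the channel center.
* ``colloid-depth-sweep`` — the same channel at depths 2–5 kBT, analysed
  for the m = 2 start class.
* ``hopper-fig3b`` — unidirectional 5-level stepwise current trace.
* ``hairpin-1int`` / ``hairpin-2int`` — two-extreme force traces with one or
  two hidden intermediate levels.

The colloid diffusivity (0.15 µm²/s, the hydrodynamically confined value for a ~0.5 µm
sphere in a ~0.9 µm channel) and the chain
rates for the hopper/hairpin systems are illustrative choices that give
well-separated dwells; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscapes import PotentialLandscape, make_channel_landscape
from .simulate import (MarkovChainSpec, SignalTrace, Trajectory,
                       generate_hairpin_trace, generate_hopper_trace,
                       simulate_langevin_ensemble)

__all__ = ["ColloidPreset", "HopperPreset", "HairpinPreset",
           "COLLOID_FIG1", "COLLOID_DEPTH_SWEEP", "HOPPER_FIG3B",
           "HAIRPIN_1INT", "HAIRPIN_2INT", "get_preset", "PRESETS"]


@dataclass(frozen=True)
class ColloidPreset:
    name: str
    n_wells: int = 4
    depth: float = 3.0
    channel_length: float = 4.8      # µm
    well_width: float = 0.42         # µm (Gaussian sigma)
    exit_barrier_extra: float = 2.0  # kBT above well depth at the exits
    grid_step: float = 0.01          # µm
    D: float = 0.15                  # µm²/s (confined channel value)
    frame_interval: float = 1.0 / 60
    sim_substeps: int = 20
    start_x: float = 2.4             # channel center
    max_time: float = 600.0          # s
    n_trajectories: int = 2000

    @property
    def sim_step(self) -> float:
        return self.frame_interval / self.sim_substeps

    def landscape(self, depth: float | None = None) -> PotentialLandscape:
        return make_channel_landscape(
            self.n_wells, self.depth if depth is None else depth,
            self.channel_length, self.well_width, self.grid_step,
            exit_barrier_extra=self.exit_barrier_extra, label=self.name)

    def simulate(self, seed: int, n_trajectories: int | None = None,
                 depth: float | None = None,
                 max_time: float | None = None) -> list[Trajectory]:
        return simulate_langevin_ensemble(
            self.landscape(depth), self.D, self.sim_step,
            self.frame_interval, self.start_x,
            self.max_time if max_time is None else max_time,
            self.n_trajectories if n_trajectories is None else n_trajectories,
            seed)


@dataclass(frozen=True)
class HopperPreset:
    """Unidirectional multi-foothold current trace; one cycle = one cargo
    ratcheted from the first to the last foothold."""

    name: str
    n_levels: int = 5
    rate: float = 5.0                # 1/s per hop
    level_means: tuple = (40.0, 35.0, 30.0, 25.0, 20.0)   # pA, blockade grows
    noise_sd: float = 0.6            # pA
    frame_interval: float = 0.005    # s
    n_cycles: int = 8000

    def chain(self) -> MarkovChainSpec:
        return MarkovChainSpec.unidirectional(self.n_levels, self.rate)

    def trace(self, seed: int, n_cycles: int | None = None) -> SignalTrace:
        return generate_hopper_trace(
            self.chain(), np.asarray(self.level_means), self.noise_sd,
            self.frame_interval, seed,
            n_cycles=self.n_cycles if n_cycles is None else n_cycles)


@dataclass(frozen=True)
class HairpinPreset:
    """Hopping-mode force trace between folded/unfolded force extremes with
    hidden intermediate levels."""

    name: str
    n_intermediates: int = 1
    force_levels: tuple = (10.0, 12.0, 14.0)   # pN, unfolded -> folded
    k_open: float = 3.0              # 1/s, leaving the unfolded state
    k_mid: float = 12.0              # 1/s, leaving an intermediate (per side)
    k_close: float = 30.0            # 1/s, leaving the folded state
    ou_relaxation: float = 5e-5      # s (bead relaxation, stiff trap)
    noise_sd: float = 0.4            # pN
    frame_interval: float = 5e-5     # s (20 kHz sampling)
    total_time: float = 400.0        # s
    epsilon: float = 0.005           # opposite-extreme quantile fraction

    def chain(self) -> MarkovChainSpec:
        """Reversible chain with long-lived extremes and fleeting
        intermediates (the intermediates sit high in free energy, which is
        why step fitting cannot resolve them in the noisy trace)."""
        n = self.n_intermediates + 2
        fw = np.full(n - 1, self.k_mid)
        bw = np.full(n - 1, self.k_mid)
        fw[0] = self.k_open       # unfolded -> first intermediate
        bw[-1] = self.k_close     # folded -> last intermediate
        return MarkovChainSpec(n_states=n, forward_rates=fw,
                               backward_rates=bw)

    @property
    def start_threshold(self) -> float:
        """Start region: force below the midpoint between the unfolded level
        and the first intermediate (the 'blue line')."""
        return 0.5 * (self.force_levels[0] + self.force_levels[1])

    def trace(self, seed: int, total_time: float | None = None) -> SignalTrace:
        return generate_hairpin_trace(
            self.n_intermediates, np.asarray(self.force_levels), self.chain(),
            self.ou_relaxation, self.noise_sd, self.frame_interval, seed,
            total_time=self.total_time if total_time is None else total_time)


COLLOID_FIG1 = ColloidPreset(name="colloid-fig1")

#: Depth sweep analysed for the m = 2 start class; per-depth absorption caps
#: scale with the expected exponential slow-down of escape.
COLLOID_DEPTH_SWEEP = {
    2.0: ColloidPreset(name="colloid-depth-sweep-2", depth=2.0,
                       max_time=600.0, n_trajectories=1000),
    3.0: ColloidPreset(name="colloid-depth-sweep-3", depth=3.0,
                       max_time=600.0, n_trajectories=1000),
    4.0: ColloidPreset(name="colloid-depth-sweep-4", depth=4.0,
                       max_time=2000.0, n_trajectories=1000),
    5.0: ColloidPreset(name="colloid-depth-sweep-5", depth=5.0,
                       max_time=5000.0, n_trajectories=1000),
}

HOPPER_FIG3B = HopperPreset(name="hopper-fig3b")

HAIRPIN_1INT = HairpinPreset(name="hairpin-1int")
HAIRPIN_2INT = HairpinPreset(
    name="hairpin-2int", n_intermediates=2,
    force_levels=(10.0, 11.6, 13.2, 14.8))

PRESETS = {
    "colloid-fig1": COLLOID_FIG1,
    "hopper-fig3b": HOPPER_FIG3B,
    "hairpin-1int": HAIRPIN_1INT,
    "hairpin-2int": HAIRPIN_2INT,
    **{f"colloid-depth-sweep-{int(d)}": p
       for d, p in COLLOID_DEPTH_SWEEP.items()},
}


def get_preset(name: str):
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset '{name}'; available: "
                       f"{sorted(PRESETS)}") from None
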