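"""Synthetic dynamics and analytic oracles.

Three generators feed the first-passage analysis with data whose ground
truth is known:

* overdamped Langevin (Euler–Maruyama) diffusion in a 1D potential with
  absorbing channel exits — the colloid-in-channel stand-in;
* continuous-time Markov jump chains (exact Gillespie sampling) — the
  discrete-state picture behind the integer-exponent law;
* noisy signal traces built on a jump chain: stepwise "hopper" current
  levels and Ornstein–Uhlenbeck-smoothed "hairpin" force levels.

:func:`hypoexp_fpt_pdf` is the exact first-passage density of a
unidirectional chain (a hypoexponential / phase-type density) and serves as
the closed-form oracle: its short-time behaviour is
``f(t) = (prod rates) t^{n-1}/(n-1)! + O(t^n)``, i.e. a power law whose
log-log slope counts the intermediate states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal, stats

from .landscapes import PotentialLandscape

__all__ = [
    "Trajectory",
    "MarkovChainSpec",
    "SignalTrace",
    "ChainRealizations",
    "simulate_langevin",
    "simulate_langevin_ensemble",
    "simulate_jump_chain",
    "hypoexp_fpt_pdf",
    "generate_hopper_trace",
    "generate_hairpin_trace",
]


@dataclass
class Trajectory:
    """Uniformly sampled 1D positions; terminates at the first recorded frame
    outside the exits (that frame is included as the last sample)."""

    frame_interval: float
    positions: np.ndarray
    trajectory_id: int = 0
    start_index: int = 0
    seed: int | None = None
    landscape_ref: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.frame_interval

    @property
    def n_frames(self) -> int:
        return len(self.positions)


@dataclass
class MarkovChainSpec:
    """Nearest-neighbour continuous-time Markov chain on states 0..n_states-1.

    ``forward_rates[i]`` is the rate i -> i+1, ``backward_rates[i]`` the rate
    i+1 -> i (zero for unidirectional chains).  ``absorbing`` states have
    their outgoing rates ignored; first entry into one ends a realization.
    """

    n_states: int
    forward_rates: np.ndarray
    backward_rates: np.ndarray
    absorbing: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.forward_rates = np.asarray(self.forward_rates, dtype=float)
        self.backward_rates = np.asarray(self.backward_rates, dtype=float)
        self.absorbing = frozenset(self.absorbing)
        n = self.n_states
        if self.forward_rates.shape != (n - 1,) or \
                self.backward_rates.shape != (n - 1,):
            raise ValueError("need n_states-1 forward and backward rates")
        if (self.forward_rates < 0).any() or (self.backward_rates < 0).any():
            raise ValueError("rates must be >= 0")
        for s in range(n):
            if s in self.absorbing:
                continue
            out = 0.0
            if s < n - 1:
                out += self.forward_rates[s]
            if s > 0:
                out += self.backward_rates[s - 1]
            if out <= 0:
                raise ValueError(f"non-absorbing state {s} has no exit rate")

    @classmethod
    def unidirectional(cls, n_states: int, rate: float | np.ndarray
                       ) -> "MarkovChainSpec":
        """Chain 0 -> 1 -> ... -> n-1 with the last state absorbing."""
        fw = np.broadcast_to(np.asarray(rate, dtype=float),
                             (n_states - 1,)).copy()
        return cls(n_states=n_states, forward_rates=fw,
                   backward_rates=np.zeros(n_states - 1),
                   absorbing=frozenset({n_states - 1}))

    @classmethod
    def reversible(cls, n_states: int, k_forward: float, k_backward: float,
                   absorbing: tuple[int, ...] = ()) -> "MarkovChainSpec":
        return cls(n_states=n_states,
                   forward_rates=np.full(n_states - 1, float(k_forward)),
                   backward_rates=np.full(n_states - 1, float(k_backward)),
                   absorbing=frozenset(absorbing))


@dataclass
class SignalTrace:
    """Uniformly sampled 1D signal (current in pA, force in pN, ...).

    ``true_states`` carries the hidden generating state per frame for
    synthetic traces; ``meta`` records the seed, preset parameters and any
    generator warnings so runs are reproducible from the trace alone.
    """

    frame_interval: float
    values: np.ndarray
    true_states: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.true_states is not None:
            self.true_states = np.asarray(self.true_states)
            if len(self.true_states) != len(self.values):
                raise ValueError("true_states must match values in length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

def simulate_langevin_ensemble(landscape: PotentialLandscape, D: float,
                               sim_step: float, frame_interval: float,
                               start_x: float, max_time: float,
                               n_trajectories: int, seed: int,
                               reflecting: bool = False
                               ) -> list[Trajectory]:
    """Euler–Maruyama integration of ``dx = -D U'(x) dt + sqrt(2 D dt) xi``
    (U in kBT, so the mobility is D) for an ensemble of independent walkers.

    Positions are recorded every ``frame_interval``; absorption at the exits
    is checked at recorded frames only, mirroring finite-rate video
    detection — substeps may leave and re-enter unobserved.  With
    ``reflecting=True`` the exits reflect instead (equilibrium checks).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if sim_step > frame_interval:
        raise ValueError("sim_step must be <= frame_interval")
    n_sub = int(round(frame_interval / sim_step))
    if not math.isclose(n_sub * sim_step, frame_interval, rel_tol=1e-9):
        raise ValueError("frame_interval must be an integer multiple of sim_step")
    if not landscape.contains(start_x):
        raise ValueError(f"start_x={start_x} outside the channel")
    rng = np.random.default_rng(seed)
    grid = landscape.x_grid
    F = landscape.force()
    if not np.isfinite(F).all():
        raise ValueError("non-finite force on the landscape grid")
    lo, hi = landscape.exits
    dt = sim_step
    drift = D * dt
    sigma = math.sqrt(2.0 * D * dt)
    max_frames = int(math.ceil(max_time / frame_interval))

    alive = np.arange(n_trajectories, dtype=np.int32)
    x = np.full(n_trajectories, float(start_x))
    rec_idx = [alive.copy()]
    rec_x = [x.copy()]
    rec_frame = [np.zeros(n_trajectories, dtype=np.int32)]
    for frame in range(1, max_frames + 1):
        for _ in range(n_sub):
            f = np.interp(x, grid, F)
            x = x + drift * f + sigma * rng.standard_normal(x.size)
            if reflecting:
                x = np.where(x < lo, 2 * lo - x, x)
                x = np.where(x > hi, 2 * hi - x, x)
        rec_idx.append(alive.copy())
        rec_x.append(x.copy())
        rec_frame.append(np.full(x.size, frame, dtype=np.int32))
        if not reflecting:
            out = (x <= lo) | (x >= hi)
            if out.any():
                keep = ~out
                alive = alive[keep]
                x = x[keep]
                if x.size == 0:
                    break
    all_idx = np.concatenate(rec_idx)
    all_x = np.concatenate(rec_x)
    all_frame = np.concatenate(rec_frame)
    order = np.lexsort((all_frame, all_idx))
    all_idx = all_idx[order]
    all_x = all_x[order]
    counts = np.bincount(all_idx, minlength=n_trajectories)
    pieces = np.split(all_x, np.cumsum(counts)[:-1])
    return [Trajectory(frame_interval=frame_interval, positions=p,
                       trajectory_id=i, seed=seed,
                       landscape_ref=landscape.label)
            for i, p in enumerate(pieces)]


def simulate_langevin(landscape: PotentialLandscape, D: float,
                      sim_step: float, frame_interval: float, start_x: float,
                      max_time: float, seed: int,
                      reflecting: bool = False) -> Trajectory:
    """Single-walker convenience wrapper around the ensemble integrator."""
    return simulate_langevin_ensemble(
        landscape, D, sim_step, frame_interval, start_x, max_time,
        n_trajectories=1, seed=seed, reflecting=reflecting)[0]


# ---------------------------------------------------------------------------
# Markov jump chains
# ---------------------------------------------------------------------------

@dataclass
class ChainRealizations:
    """Output of :func:`simulate_jump_chain`: per-realization state paths and
    jump times, plus first-passage samples keyed by absorbing state."""

    paths: list[tuple[np.ndarray, np.ndarray]]
    fpt: dict[int, np.ndarray]

    def all_fpt(self) -> np.ndarray:
        if not self.fpt:
            return np.empty(0)
        return np.concatenate([v for v in self.fpt.values()])


def simulate_jump_chain(spec: MarkovChainSpec, start_state: int,
                        n_realizations: int, seed: int,
                        jump_cap: int = 1_000_000) -> ChainRealizations:
    """Exact stochastic simulation: exponential waiting times, jumps chosen
    proportionally to the rates; a realization ends on first entry into an
    absorbing state (its time is the FPT sample).  A chain without
    absorbing states runs for exactly ``jump_cap`` jumps per realization
    (equilibrium/occupancy studies); one with unreachable absorption raises
    after the cap."""
    if start_state in spec.absorbing:
        raise ValueError("start_state must be non-absorbing")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    n = spec.n_states
    fw = spec.forward_rates
    bw = spec.backward_rates
    paths = []
    fpt: dict[int, list[float]] = {a: [] for a in spec.absorbing}
    for _ in range(n_realizations):
        s = start_state
        t = 0.0
        states = [s]
        times = [0.0]
        for _jump in range(jump_cap):
            kf = fw[s] if s < n - 1 else 0.0
            kb = bw[s - 1] if s > 0 else 0.0
            ktot = kf + kb
            t += rng.exponential(1.0 / ktot)
            s = s + 1 if rng.random() * ktot < kf else s - 1
            states.append(s)
            times.append(t)
            if s in spec.absorbing:
                fpt[s].append(t)
                break
        else:
            if spec.absorbing:
                raise RuntimeError(
                    f"no absorbing state reached within {jump_cap} jumps; "
                    "chain may not reach absorption from the start state")
        paths.append((np.asarray(states), np.asarray(times)))
    return ChainRealizations(
        paths=paths,
        fpt={a: np.asarray(v) for a, v in fpt.items()})


def _chain_frames(states: np.ndarray, times: np.ndarray, frame_interval: float,
                  t_end: float) -> np.ndarray:
    """Sample a jump path onto a uniform frame grid: state at each frame."""
    frames = np.arange(0.0, t_end, frame_interval)
    idx = np.searchsorted(times, frames, side="right") - 1
    return states[idx]


def hypoexp_fpt_pdf(rates, t):
    """Exact first-passage density of a unidirectional chain: the density of
    a sum of independent exponential stage times with the given rates.

    Distinct rates use the closed-form partial-fraction expansion
    ``f(t) = sum_i (prod_{j!=i} r_j/(r_j - r_i)) r_i exp(-r_i t)``;
    repeated rates fall back to the gamma density (all equal) or the
    phase-type matrix exponential (general).  Vectorised over ``t``.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one rate")
    if (rates <= 0).any():
        raise ValueError("rates must be > 0")
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    n = rates.size
    if n == 1:
        return rates[0] * np.exp(-rates[0] * t)
    if np.allclose(rates, rates[0], rtol=1e-12):
        return stats.gamma.pdf(t, a=n, scale=1.0 / rates[0])
    # pairwise-distinct check for the closed form
    sorted_r = np.sort(rates)
    if np.min(np.diff(sorted_r) / sorted_r[:-1]) > 1e-9:
        c = np.ones(n)
        for i in range(n):
            for j in range(n):
                if j != i:
                    c[i] *= rates[j] / (rates[j] - rates[i])
        out = np.einsum("i,i...->...", c * rates,
                        np.exp(-np.multiply.outer(rates, t)))
        return np.maximum(out, 0.0)
    # general phase-type: f(t) = e_0' exp(T t) t0
    T = np.diag(-rates) + np.diag(rates[:-1], k=1)
    t0 = np.zeros(n)
    t0[-1] = rates[-1]
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    out = np.array([np.exp(0) * linalg.expm(T * ti)[0] @ t0 for ti in tt])
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Signal traces
# ---------------------------------------------------------------------------

def generate_hopper_trace(spec: MarkovChainSpec, level_means,
                          noise_sd: float, frame_interval: float, seed: int,
                          n_cycles: int = 1, start_state: int = 0
                          ) -> SignalTrace:
    """Stepwise current trace from a jump chain with one signal level per
    state plus i.i.d. Gaussian noise per frame.

    A "cycle" is one run of the chain from ``start_state`` to absorption;
    ``n_cycles`` runs are concatenated (each cycle emulating a fresh cargo on
    the track) and the cycle start times are recorded in
    ``meta['cycle_starts']`` so downstream pairing never spans two cycles.
    Levels closer than one ``noise_sd`` set ``meta['overlapping_levels']``.
    """
    level_means = np.asarray(level_means, dtype=float)
    if level_means.size != spec.n_states:
        raise ValueError("need one level mean per state")
    if len(np.unique(level_means)) != level_means.size:
        raise ValueError("level means must be distinct")
    rng = np.random.default_rng(seed)
    real = simulate_jump_chain(spec, start_state, n_cycles,
                               seed=int(rng.integers(2 ** 31)))
    states_parts = []
    cycle_starts = [0.0]
    t_offset = 0.0
    for states, times in real.paths:
        # hold the absorbing state for a few frames so the final level shows
        t_end = times[-1] + 3 * frame_interval
        states_parts.append(_chain_frames(states, times, frame_interval, t_end))
        t_offset += len(states_parts[-1]) * frame_interval
        cycle_starts.append(t_offset)
    true_states = np.concatenate(states_parts)
    values = level_means[true_states]
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(values.size)
    meta = {
        "kind": "hopper",
        "cycle_starts": cycle_starts[:-1],
        "level_means": level_means.tolist(),
        "noise_sd": float(noise_sd),
        "overlapping_levels":
            bool(np.min(np.diff(np.sort(level_means))) < noise_sd),
    }
    return SignalTrace(frame_interval=frame_interval, values=values,
                       true_states=true_states, seed=seed, meta=meta)


def generate_hairpin_trace(n_intermediates: int, force_levels,
                           rates: MarkovChainSpec, ou_relaxation: float,
                           noise_sd: float, frame_interval: float, seed: int,
                           total_time: float = 200.0, start_state: int = 0
                           ) -> SignalTrace:
    """Two-extreme force trace with hidden intermediates: a reversible jump
    chain over ``n_intermediates + 2`` states whose per-frame force is an
    Ornstein–Uhlenbeck process relaxing toward the current state's level.

    The OU process has relaxation time ``ou_relaxation`` and stationary
    standard deviation ``noise_sd``; over a frame it is the exact AR(1)
    recursion ``f_k = mu_k + a (f_{k-1} - mu_{k-1-ish}) + s xi`` with
    ``a = exp(-dt/tau)``.
    """
    if ou_relaxation <= 0:
        raise ValueError("ou_relaxation must be > 0")
    force_levels = np.asarray(force_levels, dtype=float)
    if force_levels.size != n_intermediates + 2:
        raise ValueError("need n_intermediates + 2 force levels")
    if not (np.diff(force_levels) > 0).all():
        raise ValueError("force levels must increase from unfolded to folded")
    if rates.n_states != n_intermediates + 2:
        raise ValueError("rate spec must have n_intermediates + 2 states")
    if rates.absorbing:
        raise ValueError("hairpin dynamics must be reversible (no absorption)")
    rng = np.random.default_rng(seed)
    # One long reversible realization, capped by total_time.
    n_frames = int(round(total_time / frame_interval))
    s = start_state
    t = 0.0
    states = [s]
    times = [0.0]
    n = rates.n_states
    while t < total_time:
        kf = rates.forward_rates[s] if s < n - 1 else 0.0
        kb = rates.backward_rates[s - 1] if s > 0 else 0.0
        ktot = kf + kb
        t += rng.exponential(1.0 / ktot)
        s = s + 1 if rng.random() * ktot < kf else s - 1
        states.append(s)
        times.append(t)
    true_states = _chain_frames(np.asarray(states), np.asarray(times),
                                frame_interval, n_frames * frame_interval)
    mu = force_levels[true_states]
    a = math.exp(-frame_interval / ou_relaxation)
    s_frame = noise_sd * math.sqrt(1.0 - a * a)
    # AR(1) via lfilter: f_k = a f_{k-1} + (1-a) mu_k + s xi_k
    drive = (1.0 - a) * mu + s_frame * rng.standard_normal(mu.size)
    zi = signal.lfiltic([1.0], [1.0, -a], [mu[0]])
    values, _ = signal.lfilter([1.0], [1.0, -a], drive, zi=zi)
    meta = {
        "kind": "hairpin",
        "force_levels": force_levels.tolist(),
        "noise_sd": float(noise_sd),
        "ou_relaxation": float(ou_relaxation),
        "n_intermediates": int(n_intermediates),
    }
    return SignalTrace(frame_interval=frame_interval, values=values,
                       true_states=true_states, seed=seed, meta=meta)
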