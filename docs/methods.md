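# Methods

## The model

A particle (or molecular configuration coordinate) moves through a 1D energy
landscape with metastable wells and escapes through absorbing exits.  When
the dwell time in each well greatly exceeds the time spent moving between
wells, the dynamics coarse-grain to a nearest-neighbour Markov jump chain,
and the first-passage-time (FPT) density from a start state to absorption
behaves at short times as a power law,

    ln P(t) ≃ m · ln t + C,

where `m` is the number of intermediate states on the shortest path: the
fastest passages are those that make the minimum number of hops back-to-back,
and the density of a sum of `m+1` independent exponential stage times rises
as `t^m`.  The linear regime ends at a time Δt set by the escape rate of a
single stage, which follows Kramers scaling `exp(ΔU/kBT)` in the well depth
ΔU.  Measuring the short-time log-log slope therefore counts intermediates;
measuring Δt (after calibrating the per-m prefactor `a_m` in
`ln Δt = ΔU/kBT + ln a_m`) estimates the depth.

## Estimating the short-time exponent

The FPT samples are binned logarithmically (8 bins/decade by default) and
normalized to a density; per-bin errors of `ln P` come from a block
bootstrap that resamples whole trajectories (restart events within one
trajectory are strongly dependent), with a Poisson `1/sqrt(count)` fallback
for independent samples.

The fitted model over the pre-peak window is

    ln P = C + B ln t + c t,   c ≤ 0,

by weighted least squares (statsmodels WLS).  The reported slope is `B`, the
t → 0 exponent.  The `c t` term is the exact leading correction for a sum of
exponential stages (for an Erlang density it is exact at all orders), and
removes the downward bias a plain straight line picks up as the window
approaches the distribution's peak.  A fitted `c > 0` indicates an
ill-conditioned fit and drops the term.

The automatic window:

1. spans occupied bins above the time-resolution floor (2 frame intervals),
   skipping the first 2 occupied bins;
2. requires per-bin counts of at least `max(2, 1e-4 × total events)` — the
   relative floor keeps the window start from crawling into the sparse
   very-short-time deviation flank as statistics grow;
3. ends at the bin before the distribution's mode (for monotone densities,
   the bin holding the 75th percentile);
4. iteratively trims leading bins belonging to the very-short-time deviation
   region: while the leading 3-bin chord slope exceeds, by more than 1.5, a
   reference exponent fitted to the trailing half of the window (which is
   always past the flank), the first bin is dropped.  This operationalises
   the exclusion of direct, transit-limited passages from the linear fit;
5. reports the chi-square consistency of the final window (`homogeneous`).

`slope_se` is the WLS standard error; `bootstrap_slope_se` replaces it with
a whole-trajectory bootstrap SD (refit on fixed window bins), which is the
honest uncertainty for correlated restart data and is what the pipeline
reports.  `inferred_m = round(max(B, 0))`; the `integer_flag` additionally
requires `|B − inferred_m| ≤ 0.25` and `slope_se ≤ 0.25`.

The regime length Δt is measured against the plain straight line drawn
through the window (the line one would draw on a log-log plot): the
deviation time is where the full fitted curve falls below that line by
twice the typical per-bin error half-width, located on the smooth fits
rather than on raw bins to remove bin-level shot noise; `Δt = t_dev −
t_start`, right-censored at the last occupied bin when no deviation occurs.

`DepthScaling` fits `ln Δt = ΔU/kBT + ln a_m` per m with the slope fixed at
1 (the exponential law; the free-slope fit is kept as a diagnostic) and
predicts depths as `ΔU = ln Δt − ln a_m`.

## Synthetic study systems

All generators draw from one explicitly seeded `numpy` generator per run and
are bit-reproducible from `(preset, seed)`.

**Colloid in a channel** (`colloid-fig1`, `colloid-depth-sweep-*`).
Overdamped Langevin dynamics `dx = −D U′(x) dt + sqrt(2 D dt) ξ`
(Euler–Maruyama, U in kBT so the mobility is D), integrated at 20 substeps
per frame, recorded at 60 Hz, absorbed at the first *recorded* frame outside
the exits — reproducing the discretisation bias of video detection.  The
landscape is a 4.8 µm channel with four overlapping Gaussian wells
(σ = 0.42 µm at 1.2 µm spacing, giving smooth saddles with no flat barrier
tops) rescaled so the escape-relevant depth equals the nominal value, with
partial ghost wells beyond the exits tuned so the exit barriers sit 2 kBT
above the well depth (a moderately rate-limiting final stage).
D = 0.15 µm²/s, the hydrodynamically confined value for a ~0.5 µm sphere in
a ~0.9 µm channel.  Presets: depth 3 kBT with 2000 trajectories released at
the channel centre (the four-well closed loop), and depths 2–5 kBT analysed
for the m = 2 class (the depth sweep), with absorption caps of 600–5000 s
scaled to the expected slow-down.

These are the conditions under which the integer-exponent phenomenology is
*resolvable* in 1D overdamped dynamics.  The separation between the
diffusive transit (the "very short time deviation" region) and the dwell
time is only ~`(π/4)·ΔU·e^{−ΔU}` for smooth landscapes, so at 3 kBT the
regime is intrinsically narrow; flat-topped barriers or unconfined
diffusivities destroy it entirely.  Known residual effects at depth 3: the
m = 1 class reads high by ~+0.2–0.4 (transit contamination from the two
flanking regions), and the m = 3 class — whose short-time flank is carried
by a handful of fast trajectories — has a seed-to-seed spread of ~±0.5 even
at several thousand trajectories.

**Molecular hopper** (`hopper-fig3b`).  A unidirectional 5-foothold chain at
5 hops/s; each cycle (one cargo ratcheted along the track) emits a stepwise
current trace at 200 Hz with 5 pA steps and 0.6 pA Gaussian noise (8 σ
separation), 8000 cycles by default.  Levels are segmented by threshold
partition; with this separation no dwell merge is applied (merging deletes
genuine fast dwell pairs and deforms the short-time density — the
`min_dwell` merge in `segment_levels` remains available for noisier data).
All foothold pairs separated by m intermediates are pooled; pairs
interrupted by a cycle boundary are censored, never emitted.

**DNA hairpin** (`hairpin-1int`, `hairpin-2int`).  A reversible chain over
`m + 2` force levels with long-lived extremes and fleeting, high-free-energy
intermediates (leaving rates 3/s from unfolded, 30/s from folded, 12/s per
side from an intermediate), probed slightly above coexistence (folded
occupancy ≈ 9%).  The per-frame force is an exact AR(1) Ornstein–Uhlenbeck
process relaxing to the current state's level (σ = 0.4 pN, relaxation
50 µs, 20 kHz sampling).  The folding FPT is computed with the restart rule
from the low-force start region to the (1 − ε) opposite-extreme quantile
(ε = 0.5%).  Trace fits exclude t < 3 ms — below a few noise correlation
times a "passage" is an artefact of the fluctuating signal, the trace
analogue of the colloid's transit exclusion.  The 2-intermediate slope
reads ≈ 1.6 rather than 2 (the window's tail runs into the slow approach to
the peak); it still resolves `inferred_m = 2` reliably on ≥ 1500 s traces.

## What the generators do and do not emulate

They reproduce the statistical structure the analysis relies on: Markovian
dynamics in a fixed landscape, uniform sampling, detection-limited
absorption, state-dependent signal levels with realistic noise, restart-rule
dependence within trajectories.  They do not model hydrodynamic wall
corrections, position-dependent diffusivity, instrument drift, bead-tether
mechanics or pore electrostatics; passing tests therefore validate the
inference chain, not any particular instrument model.

## Numerical choices and degenerate inputs

- Energies in kBT throughout (kBT = 1 internally).
- Zero-count histogram bins invert to NaN (never extrapolated); well
  detection interpolates across ≤ 2 consecutive undefined bins and raises
  otherwise.  Well depth uses the lower flanking barrier (escape-relevant).
  Prominence threshold 0.5 kBT by default.
- Regions and histogram bins are half-open `[left, right)`; positions on a
  boundary belong to the region to their right.
- Distribution bins: `t_min · 10^{k/bpd}`; the builder refuses fewer than
  50 events; identical samples produce a single narrow bin.
- Bootstrap default 500 replicates at the 68% (1 σ) level for error bars;
  the fit requires ≥ 4 occupied window bins; ties in window selection are
  not possible (single anchored window).
- Chains without absorbing states run a fixed jump cap (equilibrium
  studies); unreachable absorption raises after the cap.

## Problem sizes used by the packaged analyses

Unit tests use 150–1000 trajectories or 10⁴ chain samples per case; the
closed-loop validation uses 2000 trajectories for the four-well channel,
500–1000 per depth for the sweep, 8000 hopper cycles, and 1000–1500 s
hairpin traces; `scripts/acceptance.py` uses 8000 trajectories for the
outermost colloid class (its flank is trajectory-limited), 1000 per sweep
depth, and ≥ 10⁵ recorded positions for the inversion loop.  These sizes
were chosen so that each quantity's sampling error is small compared to the
effect being demonstrated while the full suite remains a desk-scale
computation.

## Known limitations

- At 3 kBT the short-time regime overlaps the transit flank; slopes for
  m ≥ 1 carry systematic offsets of a few tenths (see above).  Deeper wells
  (≥ 4 kBT) give textbook behaviour.
- Δt depends on the documented deviation rule; only ratios and the
  exponential depth *law* (not absolute Δt values) are meaningful.
- The depth calibration transfers only between systems with the same
  geometry and diffusivity (the prefactor `a_m` is system-specific).
- The hairpin quantile target couples the noise bandwidth to the analysis
  floor: at sampling rates comparable to the noise correlation time the
  excursion stage aliases into an apparent extra state.
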