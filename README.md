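# firstpassage

Reading features of an unknown energy landscape — the number of intermediate
metastable states and the depth of its wells — directly from first-passage-time
(FPT) distributions.

## The idea

For a process that hops through a 1D ladder of discrete states, the density of
first-passage times from state *A* to state *B* behaves at short times as

```
ln P(t_FPT) ≃ (B − A − 1) ln t_FPT + C
```

i.e. a power law whose log-log slope equals *m*, the number of intermediate
states crossed on the shortest path.  The extent Δt of that linear regime grows
as `exp(ΔU/kBT)` with the well depth ΔU.  A purely dynamic measurement — the
full FPT distribution — therefore reveals two static features of the landscape:
how many minima lie en route, and how deep they are.

This package implements that analysis end to end, together with the synthetic
systems needed to validate it without experimental data:

- **`landscapes`** — 1D channel potentials with absorbing exits; Boltzmann
  inversion `U(x) = −kBT ln P(x)` of position histograms; well/boundary
  detection; *m*-class assignment of starting positions.
- **`simulate`** — overdamped Langevin (Euler–Maruyama) colloid trajectories,
  exact Markov jump chains, the closed-form hypoexponential (phase-type) FPT
  density as analytic oracle, and noisy molecular signal traces (stepwise
  nanopore "hopper" currents, Ornstein–Uhlenbeck-smoothed hairpin force
  traces).
- **`fpt`** — restart-rule event extraction (every recorded position is a new
  starting point), m-class pooling over both exits, log-binned densities with
  whole-trajectory block-bootstrap confidence intervals.
- **`regime`** — statsmodels-style model classes: `ShortTimePowerLaw` fits
  `ln P = C + B ln t + c t` over the pre-peak window (`B` is the short-time
  exponent; the `c t` term absorbs the exponential cutoff) and returns a
  results object with the slope, its standard error, the inferred intermediate
  count and the regime length; `DepthScaling` calibrates
  `ln Δt = ΔU/kBT + ln a_m` and inverts it into a depth estimate.
- **`traces`** — the two molecular readouts: quantile-target FPTs between
  force extremes, and level segmentation with pooled multi-hop FPTs.
- **`pipeline` / `cli`** — end-to-end preset analyses and a thin
  `firstpassage` command-line tool.

## Worked example

Simulate the packaged four-well channel (depth 3 kBT, 4.8 µm, 60 Hz frames),
pool restart events of the class that must cross one intermediate well, and
fit the short-time regime:

```python
from firstpassage import presets, fpt, regime

p = presets.COLLOID_FIG1
landscape = p.landscape()
trajs = p.simulate(seed=42, n_trajectories=500)
events, summary = fpt.extract_fpt_events_ensemble(trajs, landscape)
sel = fpt.select_events(events, m=1, sides="both")
dist = fpt.bootstrap_ci(sel, n_boot=200, seed=1)
fit = regime.ShortTimePowerLaw(dist, min_count_frac=1e-4).fit()
fit.regime_length()
print(fit.summary())
```

```
Short-time power-law regime fit
==============================================
slope (B - A - 1)         1.1303 +/- 0.0606
intercept C              -7.0250
cutoff coefficient       -0.0511 1/s
window [s]            [1.339, 10.04]
bins in fit                    8
R^2                       0.9984
consistent window           True
inferred m                     1  (integer_flag=True)
regime length delta_t      14.45 s
```

The slope reads ≈ 1 — one intermediate well between this start region and the
exit — and the regime length Δt feeds the depth calibration.  The same fit on
the class crossing two wells gives a slope ≈ 2, and on a synthetic hairpin
force trace with one hidden intermediate a slope ≈ 1, with
`fit.inferred_m` the rounded state count.

The CLI mirrors this:

```bash
firstpassage pipeline --preset hairpin-1int --seed 7 --out runs/hairpin
```

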