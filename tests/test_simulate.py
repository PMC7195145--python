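import numpy as np
import pytest
from scipy import stats

from firstpassage.landscapes import make_channel_landscape
from firstpassage.simulate import (MarkovChainSpec, generate_hairpin_trace,
                                   generate_hopper_trace, hypoexp_fpt_pdf,
                                   simulate_jump_chain,
                                   simulate_langevin,
                                   simulate_langevin_ensemble)


class TestLangevin:
    def test_free_diffusion_msd(self, flat_channel):
        """Ensemble MSD of pre-exit segments equals 2Dt on a flat landscape."""
        ls = make_channel_landscape(0, 0.0, 100.0, grid_step=0.1)
        D = 0.1
        trajs = simulate_langevin_ensemble(
            ls, D=D, sim_step=1 / 1200, frame_interval=1 / 60, start_x=50.0,
            max_time=1.0, n_trajectories=1000, seed=5)
        x = np.array([t.positions for t in trajs])
        for lag_frames in (6, 30, 60):
            disp2 = (x[:, lag_frames] - 50.0) ** 2
            t = lag_frames / 60
            se = disp2.std(ddof=1) / np.sqrt(len(disp2))
            assert abs(disp2.mean() - 2 * D * t) < 3 * se

    def test_reflecting_well_reaches_boltzmann_occupancy(self):
        """Long reflected runs in a single well sample exp(-U)."""
        ls = make_channel_landscape(1, 3.0, 2.0, well_width=0.3)
        trajs = simulate_langevin_ensemble(
            ls, D=0.3, sim_step=1 / 1200, frame_interval=1 / 60, start_x=1.0,
            max_time=200.0, n_trajectories=50, seed=6, reflecting=True)
        pos = np.concatenate([t.positions[60:] for t in trajs])
        edges = np.linspace(0.0, 2.0, 41)
        counts, _ = np.histogram(pos, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        U_meas = -np.log(counts / counts.sum())
        U_true = np.interp(centers, ls.x_grid, ls.U)
        ok = counts >= 500
        diff = U_meas - U_true
        assert np.max(np.abs(diff[ok] - diff[ok].mean())) < 0.25

    @staticmethod
    def _exact_mfpt(ls, D, x0):
        """Quadrature oracle: solve D tau'' - D U' tau' = -1, tau=0 at the
        absorbing ends (exact mean first-passage time)."""
        x, U = ls.x_grid, ls.U
        h = x[1] - x[0]
        n = len(x)
        Up = np.gradient(U, x)
        A = np.zeros((n - 2, n - 2))
        b = np.full(n - 2, -1.0)
        for i in range(1, n - 1):
            j = i - 1
            A[j, j] = -2 * D / h ** 2
            if j > 0:
                A[j, j - 1] = D / h ** 2 + D * Up[i] / (2 * h)
            if j < n - 3:
                A[j, j + 1] = D / h ** 2 - D * Up[i] / (2 * h)
        tau = np.linalg.solve(A, b)
        return float(np.interp(x0, x[1:-1], tau))

    def test_escape_times_match_exact_mfpt_oracle(self):
        """Simulated mean escape at depths 2 and 4 kBT agrees with the
        exact MFPT quadrature; the depth ratio follows the oracle (Kramers
        exponential growth with a curvature prefactor)."""
        means, exact = {}, {}
        for depth in (2.0, 4.0):
            ls = make_channel_landscape(1, depth, 1.6, well_width=0.25)
            trajs = simulate_langevin_ensemble(
                ls, D=0.3, sim_step=1 / 1200, frame_interval=1 / 60,
                start_x=0.8, max_time=600.0, n_trajectories=400, seed=7)
            lo, hi = ls.exits
            frames = [t.n_frames - 1 for t in trajs
                      if t.positions[-1] <= lo or t.positions[-1] >= hi]
            assert len(frames) >= 350
            means[depth] = np.mean(frames) / 60
            exact[depth] = self._exact_mfpt(ls, 0.3, 0.8)
            # frame-resolved absorption biases the simulated time up a bit
            assert 0.9 < means[depth] / exact[depth] < 1.35
        oracle_ratio = exact[4.0] / exact[2.0]
        assert oracle_ratio > np.exp(1)  # exponential depth growth
        assert abs(means[4.0] / means[2.0] - oracle_ratio)             < 0.5 * oracle_ratio

    def test_absorption_terminates_at_recorded_frame(self, four_well):
        trajs = simulate_langevin_ensemble(
            four_well, D=0.15, sim_step=1 / 1200, frame_interval=1 / 60,
            start_x=2.4, max_time=300.0, n_trajectories=30, seed=8)
        lo, hi = four_well.exits
        for t in trajs:
            inside = (t.positions[:-1] > lo) & (t.positions[:-1] < hi)
            assert inside.all()

    def test_bit_reproducible(self, four_well):
        a = simulate_langevin(four_well, 0.15, 1 / 1200, 1 / 60, 2.4, 20.0,
                              seed=99)
        b = simulate_langevin(four_well, 0.15, 1 / 1200, 1 / 60, 2.4, 20.0,
                              seed=99)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_substep_refinement_converges(self):
        """Halving the integration substep changes escape-time summaries by
        less than the Monte-Carlo error."""
        ls = make_channel_landscape(1, 2.0, 2.0, well_width=0.3)
        out = {}
        for sub in (20, 40):
            trajs = simulate_langevin_ensemble(
                ls, D=0.3, sim_step=(1 / 60) / sub, frame_interval=1 / 60,
                start_x=1.0, max_time=300.0, n_trajectories=400, seed=11)
            frames = np.array([t.n_frames - 1 for t in trajs]) / 60
            out[sub] = (frames.mean(), frames.std(ddof=1)
                        / np.sqrt(len(frames)))
        diff = abs(out[20][0] - out[40][0])
        assert diff < 3 * np.hypot(out[20][1], out[40][1])

    def test_start_outside_channel_error(self, four_well):
        with pytest.raises(ValueError):
            simulate_langevin(four_well, 0.15, 1 / 1200, 1 / 60, 5.5, 1.0, 0)


class TestJumpChain:
    def test_single_step_exponential_mean(self):
        spec = MarkovChainSpec.unidirectional(2, 2.0)
        r = simulate_jump_chain(spec, 0, 10_000, seed=1)
        fpt = r.all_fpt()
        se = fpt.std(ddof=1) / np.sqrt(fpt.size)
        assert abs(fpt.mean() - 0.5) < 3 * se

    def test_equal_rate_chain_is_erlang(self):
        """A 4-state unidirectional chain's FPT is Erlang(3, k)."""
        spec = MarkovChainSpec.unidirectional(4, 1.5)
        fpt = simulate_jump_chain(spec, 0, 10_000, seed=2).all_fpt()
        ks = stats.kstest(fpt, stats.gamma(a=3, scale=1 / 1.5).cdf)
        assert ks.pvalue > 0.01

    def test_reflecting_chain_occupancy_matches_stationary(self):
        """Detailed-balance chain with no absorption: time-weighted state
        occupancy equals the stationary distribution pi_i ~ (kf/kb)^i."""
        spec = MarkovChainSpec(n_states=3,
                               forward_rates=np.array([2.0, 1.0]),
                               backward_rates=np.array([1.0, 2.0]))
        r = simulate_jump_chain(spec, 0, 1, seed=3, jump_cap=200_000)
        states, times = r.paths[0]
        dwell = np.diff(times)
        occ = np.bincount(states[:-1], weights=dwell, minlength=3)
        occ /= occ.sum()
        pi = np.array([1.0, 2.0, 1.0])
        pi /= pi.sum()
        np.testing.assert_allclose(occ, pi, atol=0.02)

    def test_unreachable_absorption_raises(self):
        # state 2 is absorbing but state 1 never jumps forward
        spec = MarkovChainSpec(n_states=3,
                               forward_rates=np.array([1.0, 0.0]),
                               backward_rates=np.array([1.0, 1.0]),
                               absorbing=frozenset({2}))
        with pytest.raises(RuntimeError):
            simulate_jump_chain(spec, 0, 2, seed=4, jump_cap=500)

    def test_matches_hypoexponential_oracle(self):
        """Unidirectional-chain FPT samples follow the closed-form
        phase-type density (oracle equivalence)."""
        rates = [1.0, 2.0, 3.0]
        spec = MarkovChainSpec(n_states=4,
                               forward_rates=np.array(rates),
                               backward_rates=np.zeros(3),
                               absorbing=frozenset({3}))
        fpt = simulate_jump_chain(spec, 0, 10_000, seed=5).all_fpt()

        ts = np.linspace(0, 20, 2001)
        from scipy.integrate import cumulative_trapezoid
        cdf_y = cumulative_trapezoid(hypoexp_fpt_pdf(rates, ts), ts,
                                     initial=0)
        ks = stats.kstest(fpt, lambda q: np.interp(q, ts, cdf_y))
        assert ks.pvalue > 0.01


class TestHypoexp:
    def test_single_rate_is_exponential(self):
        t = np.array([0.0, 0.3, 1.0])
        np.testing.assert_allclose(hypoexp_fpt_pdf([2.0], t),
                                   2.0 * np.exp(-2.0 * t))

    def test_erlang_value(self):
        val = hypoexp_fpt_pdf([1.0, 1.0, 1.0], 0.01)
        assert val == pytest.approx(0.01 ** 2 * np.exp(-0.01) / 2, rel=1e-12)

    def test_short_time_leading_term(self):
        # f(t) ~ (prod rates) t^{n-1} / (n-1)! as t -> 0
        val = hypoexp_fpt_pdf([1.0, 2.0, 3.0], 1e-3)
        assert val == pytest.approx(6 * 1e-6 / 2, rel=0.01)

    def test_repeated_and_distinct_paths_agree(self):
        t = np.linspace(0.01, 5, 30)
        near = hypoexp_fpt_pdf([1.0, 1.0 + 1e-11, 2.0], t)   # expm path
        apart = hypoexp_fpt_pdf([1.0, 1.001, 2.0], t)        # closed form
        np.testing.assert_allclose(near, apart, rtol=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hypoexp_fpt_pdf([], 1.0)
        with pytest.raises(ValueError):
            hypoexp_fpt_pdf([1.0], -0.5)
        with pytest.raises(ValueError):
            hypoexp_fpt_pdf([0.0, 1.0], 0.5)


class TestHopperTrace:
    def test_noiseless_trace_takes_level_means(self):
        spec = MarkovChainSpec.unidirectional(3, 5.0)
        tr = generate_hopper_trace(spec, [30.0, 25.0, 20.0], noise_sd=0.0,
                                   frame_interval=0.005, seed=1, n_cycles=4)
        assert set(np.unique(tr.values)) <= {30.0, 25.0, 20.0}
        np.testing.assert_array_equal(
            tr.values, np.array([30.0, 25.0, 20.0])[tr.true_states])

    def test_unidirectional_states_nondecreasing_within_cycle(self):
        spec = MarkovChainSpec.unidirectional(5, 5.0)
        tr = generate_hopper_trace(spec, [40, 35, 30, 25, 20.0], 0.6,
                                   0.005, seed=2, n_cycles=10)
        bounds = [int(round(c / 0.005)) for c in tr.meta["cycle_starts"]]
        bounds.append(len(tr.values))
        for a, b in zip(bounds[:-1], bounds[1:]):
            assert (np.diff(tr.true_states[a:b]) >= 0).all()

    @pytest.mark.parametrize("sep,floor", [(5.0, 0.985), (6.0, 0.99)])
    def test_level_recovery_scales_with_separation(self, sep, floor):
        """Per-frame maximum-likelihood level assignment approaches the
        Gaussian misclassification bound (2-sided error at sep/2 sigma)."""
        spec = MarkovChainSpec.unidirectional(5, 5.0)
        levels = 40.0 - sep * np.arange(5)
        tr = generate_hopper_trace(spec, levels, noise_sd=1.0,
                                   frame_interval=0.005, seed=3, n_cycles=50)
        assigned = np.argmin(np.abs(tr.values[:, None] - levels[None, :]),
                             axis=1)
        assert np.mean(assigned == tr.true_states) > floor

    def test_overlap_warning_flag(self):
        spec = MarkovChainSpec.unidirectional(2, 5.0)
        tr = generate_hopper_trace(spec, [1.0, 1.5], noise_sd=1.0,
                                   frame_interval=0.01, seed=4, n_cycles=2)
        assert tr.meta["overlapping_levels"]


class TestHairpinTrace:
    def _chain(self, n_states):
        return MarkovChainSpec.reversible(n_states, 20.0, 20.0)

    def test_low_noise_fast_relaxation_is_step_function(self):
        levels = np.array([10.0, 12.0, 14.0])
        tr = generate_hairpin_trace(1, levels, self._chain(3),
                                    ou_relaxation=1e-5, noise_sd=1e-6,
                                    frame_interval=0.001, seed=5,
                                    total_time=5.0)
        nearest = levels[np.argmin(np.abs(tr.values[:, None]
                                          - levels[None, :]), axis=1)]
        assert np.max(np.abs(tr.values - nearest)) < 1e-4

    def test_one_intermediate_gives_three_plateaus(self):
        tr = generate_hairpin_trace(1, [10.0, 12, 14.0], self._chain(3),
                                    1e-4, 0.3, 1e-3, seed=6, total_time=20.0)
        assert set(np.unique(tr.true_states)) == {0, 1, 2}

    def test_ou_stationary_variance(self):
        """Within a long dwell the force variance approaches noise_sd^2."""
        slow = MarkovChainSpec.reversible(3, 0.01, 0.01)
        tr = generate_hairpin_trace(1, [10.0, 12, 14.0], slow,
                                    ou_relaxation=0.002, noise_sd=0.5,
                                    frame_interval=0.001, seed=7,
                                    total_time=100.0)
        s = tr.true_states
        runs = np.flatnonzero(np.diff(s) != 0) + 1
        starts = np.concatenate(([0], runs))
        ends = np.concatenate((runs, [s.size]))
        long_runs = [(a, b) for a, b in zip(starts, ends) if b - a > 20000]
        assert long_runs
        a, b = long_runs[0]
        var = tr.values[a + 100:b].var()
        assert abs(var - 0.25) < 0.1 * 0.25 + 0.01

    def test_invalid_relaxation(self):
        with pytest.raises(ValueError):
            generate_hairpin_trace(1, [1.0, 2, 3.0], self._chain(3), 0.0,
                                   0.1, 1e-3, seed=1)
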