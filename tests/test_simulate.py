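"""Generator correctness: exactness of FBM, stable sampling, FLSM and CTRW
construction, bead-chain geometry, and the determinism contract."""

import numpy as np
import pytest
from scipy import stats

from anomdiff.errors import ParameterError
from anomdiff.scaling import sample_msd
from anomdiff.simulate import (
    BeadChainTrajectorySpec,
    StableParams,
    WaitingTimeModel,
    _fgn_autocov,
    _fgn_hosking,
    sample_stable,
    simulate_bead_chains,
    simulate_ctrw,
    simulate_fbm,
    simulate_flsm,
    simulate_observable_series,
)


class TestFbm:
    def test_h_half_is_brownian(self):
        """At H = 0.5 increments are i.i.d. N(0, dt): vanishing lag-1
        autocorrelation and unit variance per unit time."""
        inc = np.diff(simulate_fbm(0.5, 20000, seed=3).values)
        acf1 = np.corrcoef(inc[:-1], inc[1:])[0, 1]
        assert abs(acf1) < 0.03
        assert np.var(inc) == pytest.approx(1.0, rel=0.05)

    def test_variance_scaling(self):
        """Var[X(t)] = sigma^2 t^{2H}, checked by Monte Carlo at H = 0.3."""
        ends = np.array(
            [simulate_fbm(0.3, 64, sigma=1.5, seed=s).values[-1] for s in range(4000)]
        )
        ratio = np.var(ends) / (1.5**2 * 64**0.6)
        assert ratio == pytest.approx(1.0, abs=0.08)

    @pytest.mark.parametrize("hurst", [0.25, 0.5, 0.75])
    def test_covariance_matches_closed_form(self, hurst):
        """Empirical covariance over many replicates matches
        R(s,t) = (1/2)(s^2H + t^2H - |t-s|^2H) within 3 MC standard errors."""
        n = 8
        reps = 3000
        paths = np.array(
            [simulate_fbm(hurst, n, seed=s).values[1:] for s in range(reps)]
        )
        emp = paths.T @ paths / reps
        t = np.arange(1, n + 1, dtype=float)
        theory = 0.5 * (
            t[:, None] ** (2 * hurst)
            + t[None, :] ** (2 * hurst)
            - np.abs(t[:, None] - t[None, :]) ** (2 * hurst)
        )
        # MC standard error of a Gaussian covariance entry
        se = np.sqrt(
            (theory**2 + np.outer(np.diag(theory), np.diag(theory))) / reps
        )
        assert np.all(np.abs(emp - theory) < 3 * se)

    def test_hosking_fallback_matches_covariance(self):
        """The Durbin-Levinson path generator realizes the same fGn
        covariance as the circulant-embedding route."""
        n, reps, hurst = 6, 3000, 0.3
        gamma = _fgn_autocov(hurst, n)
        samples = np.array(
            [_fgn_hosking(hurst, n, np.random.default_rng(s)) for s in range(reps)]
        )
        emp = samples.T @ samples / reps
        theory = np.array([[gamma[abs(i - j)] for j in range(n)] for i in range(n)])
        se = np.sqrt((theory**2 + np.outer(np.diag(theory), np.diag(theory))) / reps)
        assert np.all(np.abs(emp - theory) < 4 * se)

    def test_determinism(self):
        a = simulate_fbm(0.3, 128, seed=11)
        b = simulate_fbm(0.3, 128, seed=11)
        c = simulate_fbm(0.3, 128, seed=12)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize("bad_h", [0.0, 1.0, -0.2, 1.5])
    def test_hurst_domain(self, bad_h):
        with pytest.raises(ParameterError):
            simulate_fbm(bad_h, 64, seed=0)

    def test_starts_at_zero(self):
        assert simulate_fbm(0.7, 16, seed=0).values[0] == 0.0


class TestStable:
    def test_gaussian_limit(self):
        """alpha = 2 with scale s is N(0, 2 s^2)."""
        x = sample_stable(StableParams(alpha_stab=2.0, scale=1.3), 200_000, seed=5)
        assert np.var(x) == pytest.approx(2 * 1.3**2, rel=0.03)

    def test_cauchy_quantiles(self):
        """alpha = 1, skew = 0 is Cauchy: median at loc, quartiles at
        loc +- scale (scipy's Cauchy quantiles as the oracle)."""
        loc, scale = 2.0, 0.7
        x = sample_stable(
            StableParams(alpha_stab=1.0, scale=scale, loc=loc), 400_000, seed=6
        )
        q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
        oracle = stats.cauchy(loc=loc, scale=scale)
        assert q50 == pytest.approx(loc, abs=0.02)
        assert q25 == pytest.approx(oracle.ppf(0.25), abs=0.03)
        assert q75 == pytest.approx(oracle.ppf(0.75), abs=0.03)

    def test_tail_index(self):
        """P(|X| > x) ~ x^{-alpha} for alpha = 0.8, via log-log regression
        of the empirical survival function over the far tail."""
        x = np.abs(sample_stable(StableParams(alpha_stab=0.8), 1_000_000, seed=7))
        grid = np.geomspace(np.quantile(x, 0.99), np.quantile(x, 0.9999), 12)
        surv = np.array([(x > g).mean() for g in grid])
        slope = np.polyfit(np.log(grid), np.log(surv), 1)[0]
        assert slope == pytest.approx(-0.8, abs=0.05)

    def test_skewed_totally_positive(self):
        """alpha < 1 with skew = 1 is totally right-skewed: no mass below loc."""
        x = sample_stable(StableParams(alpha_stab=0.6, skew=1.0), 50_000, seed=8)
        assert (x > 0).mean() > 0.999

    @pytest.mark.parametrize(
        "kwargs", [{"alpha_stab": 0.0}, {"alpha_stab": 2.5}, {"skew": 1.5},
                   {"scale": -1.0}]
    )
    def test_param_domain(self, kwargs):
        with pytest.raises(ParameterError):
            StableParams(**kwargs)


class TestFlsm:
    def test_d_zero_collapses_kernel(self):
        """alpha = 2, H = 0.5 gives d = 0: the kernel is the identity and
        increments are i.i.d. Gaussian with variance 2 scale^2 dt."""
        p = simulate_flsm(StableParams(), 0.5, 20000, oversample=1, seed=9)
        inc = np.diff(p.values)
        assert np.var(inc) == pytest.approx(2.0, rel=0.05)
        assert abs(np.corrcoef(inc[:-1], inc[1:])[0, 1]) < 0.03

    def test_determinism(self):
        s = StableParams(alpha_stab=1.6)
        a = simulate_flsm(s, 0.6, 64, seed=4)
        b = simulate_flsm(s, 0.6, 64, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_negative_memory_parameter_runs(self):
        """H < 1/alpha (anti-persistent, d < 0) yields finite paths."""
        p = simulate_flsm(StableParams(alpha_stab=1.8), 0.3, 256, seed=2)
        assert np.all(np.isfinite(p.values))

    def test_kernel_length_validation(self):
        with pytest.raises(ParameterError):
            simulate_flsm(StableParams(), 0.7, 64, kernel_len=10, oversample=1, seed=0)

    def test_endpoint_scale_is_exact(self):
        """X(T) is exactly stable with scale sigma T^H by construction:
        at alpha = 2 its variance is 2 scale^2 T^{2H}."""
        h, n = 0.7, 64
        ends = np.array(
            [simulate_flsm(StableParams(), h, n, seed=s).values[-1]
             for s in range(3000)]
        )
        assert np.var(ends) == pytest.approx(2 * n ** (2 * h), rel=0.1)


class TestCtrw:
    def test_piecewise_constant_between_jumps(self):
        """Grid values change only at recorded jump times and all waiting
        times respect the tau0 floor."""
        wt = WaitingTimeModel(beta_tail=0.6, tau0=2.0)
        p = simulate_ctrw(wt, StableParams(), t_max=500.0, grid_dt=0.5, seed=13)
        jump_times = p.meta["jump_times"]
        waits = np.diff(np.concatenate([[0.0], jump_times]))
        assert np.all(waits >= wt.tau0)
        changed = np.flatnonzero(np.diff(p.values) != 0)
        for k in changed:
            lo, hi = p.times[k], p.times[k + 1]
            assert np.any((jump_times > lo) & (jump_times <= hi))

    def test_grid_matches_jump_bookkeeping(self):
        """Each grid value equals the cumulative jump sum at or before it."""
        wt = WaitingTimeModel(beta_tail=0.8, tau0=1.0)
        p = simulate_ctrw(wt, StableParams(), t_max=200.0, grid_dt=1.0, seed=14)
        positions = np.concatenate([[0.0], np.cumsum(p.meta["jump_sizes"])])
        for t, v in zip(p.times[::13], p.values[::13]):
            k = np.searchsorted(p.meta["jump_times"], t, side="right")
            assert v == positions[k]

    def test_nearly_marginal_tail_looks_like_random_walk(self):
        """beta -> 1 with small tau0: ensemble MSD slope near 1, matching a
        plain jump-every-step random walk."""
        wt = WaitingTimeModel(beta_tail=0.95, tau0=0.1)
        paths = np.array(
            [simulate_ctrw(wt, StableParams(), 512.0, grid_dt=1.0, seed=s).values
             for s in range(200)]
        )
        msd = np.mean(paths**2, axis=0)
        t = np.arange(8, 513)
        slope = np.polyfit(np.log(t), np.log(msd[t]), 1)[0]
        # oracle: a jump-every-step Gaussian walk has exactly linear MSD
        rw = np.cumsum(np.random.default_rng(0).standard_normal((200, 512)), axis=1)
        rw_slope = np.polyfit(
            np.log(t), np.log(np.mean(rw**2, axis=0)[t - 1]), 1
        )[0]
        assert slope == pytest.approx(rw_slope, abs=0.1)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_t_max_precondition(self):
        with pytest.raises(ParameterError):
            simulate_ctrw(
                WaitingTimeModel(0.5, tau0=10.0), StableParams(), t_max=5.0, seed=0
            )

    def test_determinism(self):
        wt = WaitingTimeModel(0.7)
        a = simulate_ctrw(wt, StableParams(), 256.0, seed=21)
        b = simulate_ctrw(wt, StableParams(), 256.0, seed=21)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.meta["jump_times"], b.meta["jump_times"])


class TestBeadChains:
    def test_single_frame_equals_initial_geometry(self):
        spec = BeadChainTrajectorySpec(
            n_chains=3, beads_per_chain=5, geometry="parallel", n_frames=1
        )
        traj = simulate_bead_chains(spec, seed=1)
        assert traj.coords.shape == (1, 15, 3)
        # straight chains along x with the configured spacing in y
        assert np.allclose(traj.coords[0, :5, 0], np.arange(5) * spec.bond_length)
        assert np.allclose(traj.coords[0, 5:10, 1], spec.chain_spacing)

    def test_sixteen_parallel_chains(self):
        """Sixteen chains carry sixteen distinct labels and neighbouring
        chains sit exactly one chain-spacing apart at frame 0."""
        spec = BeadChainTrajectorySpec(
            n_chains=16, beads_per_chain=4, geometry="parallel",
            n_frames=1, chain_spacing=2.5,
        )
        traj = simulate_bead_chains(spec, seed=2)
        assert len(traj.chains) == 16
        a = traj.coords[0][traj.chain_atoms("c00")]
        b = traj.coords[0][traj.chain_atoms("c01")]
        dmin = np.min(np.linalg.norm(a[:, None] - b[None, :], axis=2))
        assert dmin == pytest.approx(2.5)

    def test_coiled_geometry_is_self_avoiding(self):
        spec = BeadChainTrajectorySpec(
            n_chains=2, beads_per_chain=15, geometry="coiled", n_frames=1,
            bond_length=1.0,
        )
        traj = simulate_bead_chains(spec, seed=3)
        for chain in traj.chains:
            pts = traj.coords[0][traj.chain_atoms(chain)]
            bonds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert np.allclose(bonds, 1.0)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 0.9 - 1e-9

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ParameterError):
            BeadChainTrajectorySpec(geometry="twisted")

    def test_determinism(self):
        spec = BeadChainTrajectorySpec(
            n_chains=2, beads_per_chain=3, geometry="coiled", n_frames=5
        )
        a = simulate_bead_chains(spec, seed=7)
        b = simulate_bead_chains(spec, seed=7)
        assert np.array_equal(a.coords, b.coords)


class TestObservableSeries:
    def test_offset_shifts_values_exactly(self):
        a = simulate_observable_series("FBM", {"hurst": 0.4}, n_steps=64, seed=5)
        b = simulate_observable_series(
            "FBM", {"hurst": 0.4}, n_steps=64, seed=5, offset=5.0
        )
        assert np.allclose(b.values - a.values, 5.0)

    def test_offset_leaves_sample_msd_unchanged(self):
        """The sample-MSD statistic uses increments only, so a constant
        offset cannot move it."""
        a = simulate_observable_series("CTRW", {"beta_tail": 0.7}, n_steps=256, seed=6)
        b = simulate_observable_series(
            "CTRW", {"beta_tail": 0.7}, n_steps=256, seed=6, offset=100.0
        )
        ma = sample_msd(a, tau_max=20)
        mb = sample_msd(b, tau_max=20)
        np.testing.assert_allclose(ma.values, mb.values, rtol=1e-10)

    def test_unknown_mechanism(self):
        with pytest.raises(ParameterError):
            simulate_observable_series("LEVY-WALK", n_steps=32, seed=0)
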