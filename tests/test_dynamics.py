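"""Survival lifetimes, VACF/Green-Kubo, bootstrap, 1/L fits, VDOS, rattling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionflow
from ionflow.constants import SPEED_OF_LIGHT_CM_FS
from ionflow.dynamics import (
    SurvivalResult,
    VACFResult,
    VDOSResult,
    bootstrap_diffusion,
    continuous_lifetime,
    finite_size_extrapolation,
    green_kubo_D,
    msd_diffusion,
    nernst_einstein,
    rattling_period,
    survival_correlation,
    vacf,
    vdos,
)
from ionflow.simulate import MarkovCNParams, generate_markov_cn_series
from ionflow.structure import ShellSeries


def shell_from_members(members, dt=1.0):
    return ShellSeries(members=[frozenset(m) for m in members],
                       cn=[len(m) for m in members], dt=dt)


class TestSurvivalCorrelation:
    def test_constant_membership_stays_at_one(self):
        sh = shell_from_members([{1, 2, 3}] * 50)
        res = survival_correlation(sh, max_lag=25)
        np.testing.assert_allclose(res.c, 1.0)

    def test_everyone_exits_first_step(self):
        members = [{2 * t, 2 * t + 1} for t in range(40)]  # fresh ids each frame
        res = survival_correlation(shell_from_members(members), max_lag=10)
        assert res.c[0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.c[1:], 0.0, atol=1e-15)

    def test_poisson_exchange_matches_exponential(self):
        k = 0.002  # fs^-1 per member; 20-member shell for run statistics
        p = MarkovCNParams(n_frames=100_000, cn_states=(20,), exit_rates=(0.0,),
                           swap_rate=k, drift_means=(0.0,))
        series = generate_markov_cn_series(p, seed=7)
        res = survival_correlation(series.shell_series(), max_lag=int(3 / k))
        expected = np.exp(-k * res.tau)
        sel = expected > 0.05
        assert np.max(np.abs(res.c[sel] - expected[sel]) / expected[sel]) < 0.05

    def test_empty_shell_everywhere_raises(self):
        sh = shell_from_members([set()] * 20)
        with pytest.raises(ValueError, match="empty"):
            survival_correlation(sh)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_c_is_nonincreasing_for_random_series(self, seed):
        rng = np.random.default_rng(seed)
        members = []
        cur = {0, 1, 2}
        nxt = 3
        for _ in range(60):
            if rng.random() < 0.3 and cur:
                cur = set(cur)
                cur.remove(next(iter(cur)))
            if rng.random() < 0.3:
                cur = set(cur) | {nxt}
                nxt += 1
            members.append(set(cur))
        if all(len(m) == 0 for m in members[:30]):
            members[0] = {99}
        res = survival_correlation(shell_from_members(members), max_lag=30)
        assert np.all(np.diff(res.c) <= 1e-15)
        assert res.c[0] == pytest.approx(1.0)


class TestContinuousLifetime:
    def test_constant_survival_integrates_to_lag_range(self):
        sh = shell_from_members([{1}] * 101)
        res = survival_correlation(sh, max_lag=100)
        assert continuous_lifetime(res) == pytest.approx(100.0)

    def test_exponential_closed_form(self):
        tau0 = 50.0
        tau = np.arange(0.0, 2000.0)
        res = SurvivalResult(tau=tau, c=np.exp(-tau / tau0),
                             trajectory_length=2000.0, n_origins=1)
        assert continuous_lifetime(res) == pytest.approx(tau0, rel=0.01)

    def test_immediate_decay_is_at_most_one_step(self):
        c = np.zeros(100)
        c[0] = 1.0
        res = SurvivalResult(tau=np.arange(100.0), c=c, trajectory_length=100.0,
                             n_origins=1)
        assert continuous_lifetime(res) <= 1.0


class TestVacf:
    def test_constant_velocity_gives_flat_speed_squared(self):
        v = np.tile([0.001, -0.002, 0.003], (500, 1))
        res = vacf(None, velocities=v, dt=1.0, max_lag_fs=100.0)
        np.testing.assert_allclose(res.vacf, np.dot(v[0], v[0]), rtol=1e-12)

    def test_ou_decay_rate(self, free_particle_long):
        cfg, traj = free_particle_long
        res = vacf(traj, 0, max_lag_fs=300.0)
        g = cfg.trans_friction
        ratio = res.vacf / res.vacf[0]
        expected = np.exp(-g * res.tau)
        sel = expected > 0.05
        assert np.max(np.abs(ratio[sel] - expected[sel])) < 0.05 * 1.0

    def test_missing_velocities_contract(self):
        from conftest import small_trajectory

        traj = small_trajectory(with_velocities=False)
        with pytest.raises(ValueError, match="velocities"):
            vacf(traj, 0)


class TestGreenKubo:
    def test_exponential_analytic_integral(self):
        g = 0.004
        tau = np.arange(0.0, 5000.0)
        res = VACFResult(tau=tau, vacf=0.7 * np.exp(-g * tau))
        assert green_kubo_D(res, 2500.0) == pytest.approx(0.7 / (3 * g), rel=0.005)

    def test_zero_vacf_gives_zero(self):
        res = VACFResult(tau=np.arange(0.0, 3000.0), vacf=np.zeros(3000))
        assert green_kubo_D(res) == 0.0

    def test_short_grid_raises(self):
        res = VACFResult(tau=np.arange(0.0, 100.0), vacf=np.ones(100))
        with pytest.raises(ValueError, match="short"):
            green_kubo_D(res, 2500.0)

    def test_gk_matches_einstein_msd_route(self, na_ion_long):
        """Independent-route consistency on the same trajectory."""
        _, sub = na_ion_long
        d_gk = green_kubo_D(vacf(sub, 0, max_lag_fs=2500.0), 2500.0)
        d_msd = msd_diffusion(sub, fit_window_fs=(500.0, 2500.0))
        assert d_msd == pytest.approx(d_gk, rel=0.10)


class TestBootstrap:
    def test_degenerate_sample(self):
        mean, sd = bootstrap_diffusion([0.3] * 10, n_resamples=1000, seed=0)
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.0, abs=1e-14)

    def test_two_point_closed_form(self):
        # resampled mean of {0,1}, n=2: SD = population SD / sqrt(2) = 0.5/sqrt(2)
        mean, sd = bootstrap_diffusion([0.0, 1.0], n_resamples=200_000, seed=1)
        assert sd == pytest.approx(0.5 / np.sqrt(2), rel=0.03)

    def test_seeded_determinism(self):
        est = list(np.random.default_rng(2).normal(size=12))
        a = bootstrap_diffusion(est, n_resamples=5000, seed=3)
        b = bootstrap_diffusion(est, n_resamples=5000, seed=3)
        assert a == b

    def test_bootstrap_mean_converges_to_sample_mean(self):
        rng = np.random.default_rng(4)
        est = rng.normal(1.0, 0.2, size=40)
        mean, sd = bootstrap_diffusion(est, n_resamples=100_000, seed=5)
        assert abs(mean - est.mean()) < 0.005 * est.std()


class TestFiniteSizeExtrapolation:
    def test_exact_line_recovers_intercept(self):
        L = np.array([10.0, 12.0, 15.0, 20.0, 30.0])
        D = 2.0 / L + 0.37
        fit = finite_size_extrapolation(np.column_stack([L, D, np.full(5, 0.01)]))
        assert fit.d_infinity == pytest.approx(0.37, abs=1e-12)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)

    def test_two_points_interpolate_exactly(self):
        fit = finite_size_extrapolation([(10.0, 0.6, 0.1), (20.0, 0.5, 0.1)])
        # line through both points: D = 2/L + 0.4
        assert fit.d_infinity == pytest.approx(0.4, abs=1e-12)

    def test_monte_carlo_coverage_of_intercept(self):
        rng = np.random.default_rng(6)
        L = np.array([10.0, 12.0, 15.0, 20.0, 30.0])
        c_true, m_true, sd = 0.5, 1.5, 0.02
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            D = m_true / L + c_true + rng.normal(0, sd, size=5)
            fit = finite_size_extrapolation(np.column_stack([L, D, np.full(5, sd)]))
            if abs(fit.d_infinity - c_true) < 2 * fit.d_infinity_se:
                hits += 1
        assert hits / n_rep > 0.90

    def test_singular_design_raises(self):
        with pytest.raises(ValueError, match="singular|equal"):
            finite_size_extrapolation([(10.0, 0.5, 0.1), (10.0, 0.6, 0.1)])


class TestNernstEinstein:
    def test_zero_diffusion(self):
        assert nernst_einstein(0.0) == 0.0

    def test_reference_value_at_300K(self):
        # F^2 * 1e-9 / (R * 300) in S m^2/mol, reported in S cm^2/mol
        assert nernst_einstein(1e-9, 300.0) == pytest.approx(37.32, abs=0.01)

    def test_linearity(self):
        assert nernst_einstein(2e-9) == pytest.approx(2 * nernst_einstein(1e-9))


class TestVdos:
    def test_pure_cosine_peaks_at_its_frequency(self):
        dt = 2.0
        nu0 = 0.01
        t = np.arange(48_000) * dt
        v = np.zeros((len(t), 3))
        v[:, 2] = 1e-3 * np.cos(2 * np.pi * nu0 * t)
        res = vdos(None, velocities=v, dt=dt, block_counts=(24, 48))
        peak = res.freq_fs[1:][np.argmax(res.intensity[1:])]
        df = res.freq_fs[1] - res.freq_fs[0]
        assert abs(peak - nu0) <= df

    def test_damped_oscillator_peak_near_natural_frequency(self):
        """Underdamped Langevin oscillator: spectrum peaks at omega0/2pi."""
        rng = np.random.default_rng(8)
        omega0, gamma, dt, kT, m = 0.05, 0.005, 1.0, 0.025, 100.0
        n = 200_000
        x, vv = 0.0, 0.0
        vs = np.empty((n, 3))
        sig = np.sqrt(2 * gamma * kT / m * dt)
        for i in range(n):
            a = -omega0**2 * x - gamma * vv
            vv += a * dt + sig * rng.standard_normal()
            x += vv * dt
            vs[i] = (0.0, 0.0, vv)
        res = vdos(None, velocities=vs, dt=dt, block_counts=(24, 48, 96))
        peak = res.freq_fs[1:][np.argmax(res.intensity[1:])]
        assert peak == pytest.approx(omega0 / (2 * np.pi), rel=0.05)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal((96_000, 3))
        res = vdos(None, velocities=v, dt=1.0, block_counts=(48, 96))
        inner = res.intensity[2:-2]
        assert inner.std() / inner.mean() < 0.25

    def test_block_shorter_than_two_frames_raises(self):
        v = np.zeros((30, 3))
        with pytest.raises(ValueError, match="block"):
            vdos(None, velocities=v, dt=1.0, block_counts=(24,))


class TestRattlingPeriod:
    def test_wavenumber_conversion_50_per_cm(self):
        nu = 50.0 * SPEED_OF_LIGHT_CM_FS  # 50 cm^-1 in fs^-1
        freq = np.linspace(0, 0.02, 200)
        intensity = np.exp(-((freq - nu) ** 2) / (2 * (5e-4) ** 2))
        res = VDOSResult(freq_fs=freq, intensity=intensity, block_counts=(1,),
                         peak_by_block_count={})
        tau = rattling_period(res)
        assert tau == pytest.approx(1.0 / (2.99792458e10 * 50.0) * 1e15, rel=0.02)
        assert tau == pytest.approx(667.1, rel=0.02)

    def test_reciprocal_of_cosine_frequency(self):
        dt = 2.0
        t = np.arange(40_000) * dt
        v = np.zeros((len(t), 3))
        v[:, 0] = np.cos(2 * np.pi * 0.01 * t)
        res = vdos(None, velocities=v, dt=dt, block_counts=(24, 48))
        assert rattling_period(res) == pytest.approx(100.0, rel=0.05)

    def test_lower_of_two_peaks_selected(self):
        freq = np.linspace(0, 0.02, 400)
        spec = (np.exp(-((freq - 0.004) ** 2) / 2e-7)
                + 2.0 * np.exp(-((freq - 0.012) ** 2) / 2e-7))
        res = VDOSResult(freq_fs=freq, intensity=spec, block_counts=(1,),
                         peak_by_block_count={})
        assert rattling_period(res) == pytest.approx(1 / 0.004, rel=0.02)

    def test_monotone_spectrum_raises(self):
        freq = np.linspace(0, 0.02, 100)
        res = VDOSResult(freq_fs=freq, intensity=np.exp(-freq / 0.003),
                         block_counts=(1,), peak_by_block_count={})
        with pytest.raises(ValueError, match="manual"):
            rattling_period(res)


# Note: lifetime ordering across the full ion presets (which differ in mass
# as well as binding) is not asserted -- Langevin drag makes D scale as 1/m,
# so the heavy labile preset's diffusion-limited residence nearly ties the
# intermediate one.  The stability dial is the well-depth multiplier at
# matched mass, covered by TestShellTunability in test_simulate.py.
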