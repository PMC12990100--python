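"""RDF normalization, first-minimum detection, smooth CN, PMF and tilt angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionflow
from ionflow.structure import (
    RDFResult,
    ShellSeries,
    compute_rdf,
    cos_to_degrees,
    detect_first_minimum,
    integer_cn_histogram,
    pmf_from_cn_series,
    shell_series,
    smooth_cn,
    tilt_angle_density,
)
from ionflow.simulate import MarkovCNParams, generate_markov_cn_series
from ionflow.trajectory import Trajectory


def uniform_gas_trajectory(n_frames=60, n_sol=150, box=20.0, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, (n_frames, n_sol + 1, 3))
    return Trajectory(
        times=np.arange(1, n_frames + 1, dtype=float),
        box_length=box,
        species=["ION"] + ["SOL"] * n_sol,
        positions=pos,
    )


class TestComputeRdf:
    def test_ideal_gas_is_flat_at_unity(self):
        traj = uniform_gas_trajectory(n_frames=200)
        rdf = compute_rdf(traj, bin_width=0.2)
        sel = rdf.r > 2.0  # skip small-r bins with tiny expected counts
        counts = rdf.g[sel] * rdf.n_frames * rdf.density * 4 * np.pi * rdf.r[sel] ** 2 * 0.2
        # Poisson: g = 1 within ~3/sqrt(expected counts) per bin
        tol = 3.0 / np.sqrt(np.maximum(counts / np.maximum(rdf.g[sel], 1e-12), 1.0))
        assert np.all(np.abs(rdf.g[sel] - 1.0) < np.maximum(tol, 0.2))

    def test_two_fixed_atoms_single_bin(self):
        d = 3.456
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = d
        traj = Trajectory(times=[1.0], box_length=50.0, species=["ION", "SOL"],
                          positions=pos)
        rdf = compute_rdf(traj, bin_width=0.03)
        nonzero = np.flatnonzero(rdf.g)
        assert len(nonzero) == 1
        lo = rdf.r[nonzero[0]] - 0.015
        assert lo <= d <= lo + 0.03

    def test_running_cn_reaches_sphere_volume_count(self):
        traj = uniform_gas_trajectory(n_frames=300, n_sol=200, box=20.0)
        rdf = compute_rdf(traj, bin_width=0.1)
        r_half = traj.box_length / 2
        expected = 4.0 / 3.0 * np.pi * rdf.density * r_half**3
        i = np.searchsorted(rdf.r, r_half) - 1
        assert rdf.running_cn[i] == pytest.approx(expected, rel=0.05)

    def test_empty_partner_selection(self):
        traj = uniform_gas_trajectory(n_frames=2)
        with pytest.raises(ValueError, match="partner"):
            compute_rdf(traj, partner_species="XX")


def synthetic_rdf(valley=3.2, noise=0.0, seed=0):
    r = np.arange(0.015, 8.0, 0.03)
    g = 2.5 * np.exp(-((r - 2.4) ** 2) / 0.08) + 1.2 * np.exp(-((r - 4.2) ** 2) / 0.5)
    # enforce the valley location by adding components around it
    g = 2.5 * np.exp(-((r - 2.4) ** 2) / 0.08) + 1.5 * np.exp(-((r - (2 * valley - 2.4)) ** 2) / 0.3)
    if noise:
        g = g + np.random.default_rng(seed).normal(0, noise, size=len(r))
    return RDFResult(r=r, g=g, running_cn=np.cumsum(g), density=0.03,
                     bin_width=0.03, n_frames=1)


class TestDetectFirstMinimum:
    def test_clean_two_gaussian_valley(self):
        rdf = synthetic_rdf(valley=3.2)
        # analytic valley of the two-Gaussian profile
        from scipy.optimize import minimize_scalar

        f = lambda x: 2.5 * np.exp(-((x - 2.4) ** 2) / 0.08) + 1.5 * np.exp(
            -((x - 4.0) ** 2) / 0.3
        )
        true_min = minimize_scalar(f, bounds=(2.4, 4.0), method="bounded").x
        r0 = detect_first_minimum(rdf)
        assert abs(r0 - true_min) <= 2 * rdf.bin_width

    def test_monotone_profile_raises(self):
        r = np.arange(0.015, 5.0, 0.03)
        rdf = RDFResult(r=r, g=np.linspace(0, 2, len(r)), running_cn=np.zeros(len(r)),
                        density=0.03, bin_width=0.03, n_frames=1)
        with pytest.raises(ValueError, match="minimum|peak"):
            detect_first_minimum(rdf)

    def test_noisy_valley_with_smoothing(self):
        clean = detect_first_minimum(synthetic_rdf())
        noisy = detect_first_minimum(synthetic_rdf(noise=0.05, seed=4))
        assert abs(noisy - clean) <= 2 * 0.03


class TestSmoothCn:
    def test_limit_at_cutoff_is_half(self):
        assert smooth_cn([1.0], 1.0) == pytest.approx(0.5)  # NN/ND = 20/40

    def test_limit_at_zero_distance_is_one(self):
        assert smooth_cn([1e-9], 1.0) == pytest.approx(1.0)

    def test_value_beyond_cutoff(self):
        # direct evaluation of (1 - 1.2^20)/(1 - 1.2^40)
        assert smooth_cn([1.2], 1.0) == pytest.approx(0.02542, abs=5e-6)

    def test_general_exponents_match_ratio_form(self):
        x = np.array([0.5, 0.9, 1.1, 1.7])
        got = smooth_cn(x, 1.0, nn=12, nd=24)
        expected = np.sum((1 - x**12) / (1 - x**24))
        assert got == pytest.approx(expected)

    @given(st.floats(0.01, 3.0), st.floats(0.01, 3.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_nonincreasing_in_distance(self, a, b):
        lo, hi = sorted((a, b))
        assert smooth_cn([lo], 1.0) >= smooth_cn([hi], 1.0)


class TestPmf:
    def test_equal_populations_give_flat_pmf(self):
        samples = np.concatenate([np.full(5000, 4.05), np.full(5000, 5.05)])
        res = pmf_from_cn_series(samples, bin_width=1.0)
        populated = res.pmf[res.counts > 0]
        np.testing.assert_allclose(populated, 0.0, atol=1e-12)

    def test_e_to_one_ratio_gives_one_kT(self):
        n = 100_000
        samples = np.concatenate([np.full(int(n * np.e / (1 + np.e)), 4.05),
                                  np.full(int(n / (1 + np.e)), 5.05)])
        res = pmf_from_cn_series(samples, bin_width=1.0)
        populated = res.pmf[res.counts > 0]
        assert populated.max() == pytest.approx(1.0, abs=2e-4)

    def test_double_well_recovery_by_inverse_sampling(self):
        """Samples drawn from a known double-well Boltzmann density recover
        the potential to 0.05 kT RMS over populated bins at 1e6 samples."""
        grid = np.linspace(2.5, 7.5, 2001)
        u = 1.5 * ((grid - 5.0) ** 2 - 1.44) ** 2 / 1.44**2  # two wells at 3.8/6.2
        p = np.exp(-u)
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        rng = np.random.default_rng(11)
        samples = np.interp(rng.random(1_000_000), cdf, grid)
        res = pmf_from_cn_series(samples, bin_width=0.1)
        # binned truth: -ln of the density mass per bin, same convention
        edges = np.concatenate([res.cn_grid - 0.05, [res.cn_grid[-1] + 0.05]])
        dens = np.exp(-u)
        mass = np.array([
            np.trapezoid(dens[(grid >= lo) & (grid < hi)], grid[(grid >= lo) & (grid < hi)])
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        sel = (res.counts > 200) & (mass > 0)
        truth = -np.log(mass[sel] / mass[sel].sum())
        truth -= truth.min()
        rec = res.pmf[sel] - res.pmf[sel].min()
        rms = np.sqrt(np.mean((rec - truth) ** 2))
        assert rms < 0.05

    def test_pmf_shape_invariant_under_sample_count(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5.0, 0.4, size=200_000)
        a = pmf_from_cn_series(base, bin_width=0.1)
        b = pmf_from_cn_series(np.repeat(base, 3), bin_width=0.1)
        sel = (a.counts > 100) & (b.counts > 100)
        np.testing.assert_allclose(a.pmf[sel], b.pmf[sel], atol=1e-6)

    def test_empty_bins_are_nan_not_zero(self):
        samples = np.concatenate([np.full(500, 3.05), np.full(500, 6.05)])
        res = pmf_from_cn_series(samples, bin_width=1.0)
        assert np.isnan(res.pmf[res.counts == 0]).all()


class TestIntegerCnHistogram:
    def test_constant_coordination(self):
        sh = ShellSeries(members=[frozenset({1, 2, 3, 4})] * 10, cn=[4] * 10, dt=1.0)
        hist = integer_cn_histogram(sh)
        assert hist == {4: 10}

    def test_markov_occupancies_recovered(self):
        p = MarkovCNParams(n_frames=100_000, cn_states=(4, 5), exit_rates=(0.01, 0.01),
                           drift_means=(0.0, 0.0))
        series = generate_markov_cn_series(p, seed=5)
        hist = integer_cn_histogram(series.shell_series())
        total = sum(hist.values())
        assert total == 100_000
        occ4 = np.mean(series.cn == 4)
        assert hist[4] / total == pytest.approx(occ4, abs=1e-12)
        assert abs(occ4 - 0.5) < 0.05  # symmetric rates -> near-equal occupancy

    def test_empty_series(self):
        sh = ShellSeries(members=[], cn=[], dt=1.0)
        assert integer_cn_histogram(sh) == {}


class TestTiltAngleDensity:
    def _traj_with_dipoles(self, n_frames, n_sol, seed, aligned=None, box=12.0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, box, (n_frames, n_sol + 1, 3))
        pos[:, 0] = box / 2
        if aligned is None:
            dip = rng.standard_normal((n_frames, n_sol + 1, 3))
            dip /= np.linalg.norm(dip, axis=2, keepdims=True)
        else:
            dip = np.tile(np.asarray(aligned, float), (n_frames, n_sol + 1, 1))
        return Trajectory(
            times=np.arange(1, n_frames + 1, dtype=float), box_length=box,
            species=["ION"] + ["SOL"] * n_sol, positions=pos, dipoles=dip,
        )

    def test_parallel_dipoles_pile_on_cos_theta_one(self):
        traj = self._traj_with_dipoles(20, 30, 0, aligned=(0, 0, 1))
        sh = shell_series(traj, r0=5.0)
        res = tilt_angle_density(traj, sh, (0, 0, 1), bins=20)
        top = res.density[:, -1]
        assert res.density[:, :-1].sum() == 0
        assert top.sum() > 0

    def test_isotropy_gives_uniform_marginals_and_no_correlation(self):
        traj = self._traj_with_dipoles(150, 60, 1)
        sh = shell_series(traj, r0=5.0)
        res = tilt_angle_density(traj, sh, (0, 0, 1), bins=10)
        n = res.n_samples
        # normalization
        cell = (2.0 / 10) ** 2
        assert res.density.sum() * cell == pytest.approx(1.0, abs=1e-10)
        assert abs(res.correlation) < 3.0 / np.sqrt(n)
        assert abs(res.leading_mean_cos_theta) < 4.0 / np.sqrt(n)

    def test_printed_cosine_to_angle_conversion(self):
        assert cos_to_degrees(0.49) == pytest.approx(60.7, abs=0.05)
        assert cos_to_degrees(0.30) == pytest.approx(72.5, abs=0.05)

    def test_zero_field_direction_needs_reference_axis(self):
        traj = self._traj_with_dipoles(5, 10, 2)
        sh = shell_series(traj, r0=5.0)
        with pytest.raises(ValueError, match="reference axis"):
            tilt_angle_density(traj, sh, (0.0, 0.0, 0.0))

    def test_no_shell_occupancy_raises(self):
        traj = self._traj_with_dipoles(5, 10, 3)
        sh = shell_series(traj, r0=1e-6)
        with pytest.raises(ValueError, match="occupancy"):
            tilt_angle_density(traj, sh, (0, 0, 1))


class TestCountingRouteConsistency:
    def test_running_cn_at_r0_matches_mean_integer_cn(self, na_bath_all):
        """The RDF-integral route and the per-frame membership route count
        the same shell population."""
        cfg, sub = na_bath_all
        rdf = ionflow.compute_rdf(sub)
        r0 = ionflow.detect_first_minimum(rdf)
        sh = ionflow.shell_series(sub, r0)
        i = np.searchsorted(rdf.r + rdf.bin_width / 2, r0)
        assert rdf.running_cn[i - 1] == pytest.approx(sh.cn.mean(), rel=0.02)
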