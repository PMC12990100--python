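"""Time-correlation analyses of ion and shell dynamics.

Continuous survival correlation of first-shell membership and its
integral lifetime, multi-origin velocity autocorrelation, Green-Kubo
diffusion constants with bootstrap errors and 1/L finite-size
extrapolation, the Nernst-Einstein molar conductivity, block-averaged
velocity density of states and the rattling period of the caged ion.

The continuous survival correlation is

    C(tau) = < S(t0, t0+tau) / N(t0) >_{t0},

where N(t0) counts first-shell members at origin t0 and S counts how many
of those remain *continuously* inside the shell cutoff up to t0+tau; its
integral over the available lag range is the continuous lifetime tau_c.
The per-origin ratio form (N inside the origin average) is used, with
origins at every frame.  No intermittent-return allowance is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    D_TO_SI,
    FARADAY,
    GAS_CONSTANT,
    SPEED_OF_LIGHT_CM_FS,
)
from .structure import ShellSeries
from .trajectory import Trajectory

__all__ = [
    "SurvivalResult",
    "VACFResult",
    "DiffusionSummary",
    "VDOSResult",
    "survival_correlation",
    "continuous_lifetime",
    "vacf",
    "green_kubo_D",
    "bootstrap_diffusion",
    "finite_size_extrapolation",
    "nernst_einstein",
    "vdos",
    "rattling_period",
    "msd_diffusion",
]

GK_UPPER_LIMIT_FS = 2500.0
N_RESAMPLES_DEFAULT = 10_000
BLOCK_COUNTS_DEFAULT = (24, 48, 96, 192, 384)


@dataclass
class SurvivalResult:
    tau: np.ndarray  # fs
    c: np.ndarray
    trajectory_length: float  # fs
    n_origins: int
    lifetime: float | None = None  # filled by continuous_lifetime


@dataclass
class VACFResult:
    tau: np.ndarray  # fs
    vacf: np.ndarray  # A^2 fs^-2 (3-vector dot product)
    diffusion: float | None = None  # A^2/fs, filled by green_kubo_D
    upper_limit: float | None = None

    @property
    def diffusion_si(self) -> float | None:
        return None if self.diffusion is None else self.diffusion * D_TO_SI


@dataclass
class DiffusionSummary:
    box_lengths: np.ndarray
    d_means: np.ndarray  # A^2/fs
    d_sds: np.ndarray
    slope: float
    d_infinity: float  # A^2/fs
    d_infinity_se: float
    molar_conductivity: float | None = None  # S cm^2/mol


@dataclass
class VDOSResult:
    freq_fs: np.ndarray  # fs^-1
    intensity: np.ndarray  # block-averaged, arbitrary units
    block_counts: tuple
    peak_by_block_count: dict
    rattling_freq: float | None = None  # fs^-1
    rattling_period: float | None = None  # fs

    @property
    def freq_cm(self) -> np.ndarray:
        return self.freq_fs / SPEED_OF_LIGHT_CM_FS


def survival_correlation(shell: ShellSeries, max_lag: int | None = None) -> SurvivalResult:
    """Continuous survival correlation of shell membership.

    For every origin with N(t0) > 0, each member contributes 1 to S(t0,tau)
    for all lags up to the end of its current uninterrupted membership run.
    Origins are restricted to t0 <= T - max_lag so every lag is equally
    sampled and runs touching the trajectory end are not censored inside
    the window.
    """
    nf = shell.n_frames
    if nf < 2:
        raise ValueError("survival correlation needs at least two frames")
    if max_lag is None:
        max_lag = nf // 2
    max_lag = int(min(max_lag, nf - 1))
    n_origins_total = nf - max_lag

    n_t = np.array([len(m) for m in shell.members])
    valid = n_t[:n_origins_total] > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("shell is empty at every usable origin; correlation undefined")

    # run-length decomposition per member: remaining[t] = frames the member
    # stays continuously present from t (inclusive), capped at max_lag.
    weight_hist = np.zeros(max_lag + 1)
    prev: dict[int, int] = {}  # member -> start frame of its current run
    runs: list[tuple[int, int, int]] = []  # (member, start, end_exclusive)
    for t in range(nf):
        cur = shell.members[t]
        for m in list(prev):
            if m not in cur:
                runs.append((m, prev.pop(m), t))
        for m in cur:
            if m not in prev:
                prev[m] = t
    for m, start in prev.items():
        runs.append((m, start, nf))

    inv_n = np.zeros(nf)
    inv_n[: n_origins_total][valid] = 1.0 / n_t[:n_origins_total][valid]
    for _, start, end in runs:
        t0_hi = min(end, n_origins_total)
        if t0_hi <= start:
            continue
        t0s = np.arange(start, t0_hi)
        remaining = np.minimum(end - 1 - t0s, max_lag)
        np.add.at(weight_hist, remaining, inv_n[t0s])

    # C(tau) = sum over contributions with remaining >= tau / n_valid
    c = np.cumsum(weight_hist[::-1])[::-1] / n_valid
    tau = np.arange(max_lag + 1) * shell.dt
    return SurvivalResult(
        tau=tau, c=c, trajectory_length=(nf - 1) * shell.dt, n_origins=n_valid
    )


def continuous_lifetime(result: SurvivalResult) -> float:
    """Continuous lifetime tau_c: trapezoidal integral of C over its lag range."""
    result.lifetime = float(np.trapezoid(result.c, result.tau))
    return result.lifetime


def _autocorr_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased multi-origin autocorrelation of a 1-D series via FFT."""
    n = len(x)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return acf.real / counts


def vacf(
    traj: Trajectory,
    atom_index: int = 0,
    max_lag_fs: float | None = None,
    velocities: np.ndarray | None = None,
    dt: float | None = None,
) -> VACFResult:
    """Multi-origin velocity autocorrelation <v(t0).v(t0+tau)> of one atom.

    Accepts either a trajectory (with velocities) or a raw (n, 3) velocity
    series with its sampling interval.
    """
    if velocities is None:
        v = traj.require_velocities()[:, atom_index, :]
        dt = traj.timestep
    else:
        v = np.asarray(velocities, dtype=float)
        if dt is None:
            raise ValueError("dt is required with a raw velocity series")
    n = v.shape[0]
    if max_lag_fs is None:
        max_lag = n // 2
    else:
        max_lag = int(round(max_lag_fs / dt))
    max_lag = min(max_lag, n - 1)
    acf = np.zeros(max_lag + 1)
    for d in range(3):
        acf += _autocorr_fft(v[:, d], max_lag)
    return VACFResult(tau=np.arange(max_lag + 1) * dt, vacf=acf)


def green_kubo_D(result: VACFResult, upper_limit_fs: float = GK_UPPER_LIMIT_FS) -> float:
    """Green-Kubo diffusion constant D = (1/3) int_0^limit VACF dtau (A^2/fs)."""
    if result.tau[-1] < upper_limit_fs - 1e-9:
        raise ValueError(
            f"VACF lag grid ends at {result.tau[-1]:.0f} fs, short of the "
            f"{upper_limit_fs:.0f} fs integration limit"
        )
    sel = result.tau <= upper_limit_fs + 1e-9
    d = float(np.trapezoid(result.vacf[sel], result.tau[sel])) / 3.0
    result.diffusion = d
    result.upper_limit = upper_limit_fs
    return d


def msd_diffusion(
    traj: Trajectory,
    atom_index: int = 0,
    fit_window_fs: tuple[float, float] | None = None,
) -> float:
    """Einstein-route D from the mean-squared-displacement slope (A^2/fs).

    Independent cross-check of the Green-Kubo estimate: MSD(t) ~ 6 D t for
    unwrapped coordinates.  The slope is fit over the stated lag window,
    by default 2.5-10 ps (the Green-Kubo integration scale, where a single
    trajectory still determines the MSD tightly); for short trajectories
    the window falls back to 10%-50% of the available lag range.
    """
    pos = traj.positions[:, atom_index, :]
    n = pos.shape[0]
    dt = traj.timestep
    max_lag = n // 2
    # FFT-based MSD
    msd = np.zeros(max_lag + 1)
    for d in range(3):
        x = pos[:, d]
        acf = _autocorr_fft(x, max_lag)
        sq = x**2
        csum = np.concatenate(([0.0], np.cumsum(sq)))
        total = csum[-1]
        counts = n - np.arange(max_lag + 1)
        sum_head = csum[n - np.arange(max_lag + 1)]
        sum_tail = total - csum[np.arange(max_lag + 1)]
        msd += (sum_head + sum_tail) / counts - 2.0 * acf
    tau = np.arange(max_lag + 1) * dt
    if fit_window_fs is None:
        if tau[-1] >= 10_000.0:
            fit_window_fs = (2500.0, 10_000.0)
        else:
            fit_window_fs = (0.1 * tau[-1], 0.5 * tau[-1])
    sel = (tau >= fit_window_fs[0]) & (tau <= fit_window_fs[1])
    slope = np.polyfit(tau[sel], msd[sel], 1)[0]
    return float(slope / 6.0)


def bootstrap_diffusion(
    estimates,
    n_resamples: int = N_RESAMPLES_DEFAULT,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap mean and SD of the mean over per-segment D estimates.

    Draws ``n_resamples`` resamples of the full sample size with
    replacement and returns (mean, SD) of the resampled means.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("bootstrap needs at least two estimates")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, est.size, size=(n_resamples, est.size))
    means = est[idx].mean(axis=1)
    return float(means.mean()), float(means.std(ddof=0))


def finite_size_extrapolation(d_by_length) -> DiffusionSummary:
    """Weighted linear fit of D against 1/L; the intercept is D_infinity.

    ``d_by_length`` holds (L, D, SD) triples; weights are 1/SD^2 (equal
    weights when any SD is zero or missing).
    """
    arr = np.asarray(d_by_length, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two box sizes")
    L, D = arr[:, 0], arr[:, 1]
    sd = arr[:, 2] if arr.shape[1] > 2 else np.zeros_like(L)
    if np.unique(L).size < 2:
        raise ValueError("all box lengths equal; 1/L design is singular")
    x = 1.0 / L
    w = 1.0 / sd**2 if np.all(sd > 0) else np.ones_like(L)
    # weighted least squares y = m x + c
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * D).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (D - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    intercept_var = 1.0 / sw + xbar**2 / sxx
    if not np.all(sd > 0):
        resid = D - (slope * x + intercept)
        dof = max(len(L) - 2, 1)
        intercept_var *= (w * resid**2).sum() / dof
    return DiffusionSummary(
        box_lengths=L,
        d_means=D,
        d_sds=sd,
        slope=float(slope),
        d_infinity=float(intercept),
        d_infinity_se=float(np.sqrt(intercept_var)),
    )


def nernst_einstein(d_infinity_si: float, temperature: float = 300.0) -> float:
    """Molar conductivity Lambda_m = F^2 D / (R T) in S cm^2 mol^-1.

    ``d_infinity_si`` is in m^2/s; the S m^2/mol result is scaled by 1e4.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lam_si = FARADAY**2 * d_infinity_si / (GAS_CONSTANT * temperature)
    return lam_si * 1e4


def vdos(
    traj: Trajectory | None = None,
    atom_index: int = 0,
    block_counts: tuple = BLOCK_COUNTS_DEFAULT,
    velocities: np.ndarray | None = None,
    dt: float | None = None,
    window: str = "hann",
) -> VDOSResult:
    """Block-averaged velocity density of states.

    For each requested block count the velocity series is split into equal
    blocks (remainder truncated), the per-block VACF is Hann-windowed and
    Fourier transformed, and the block spectra averaged.  The returned
    spectrum is the average over all block counts interpolated onto the
    finest grid; ``peak_by_block_count`` records the lowest interior peak
    per block count so its stability can be checked.
    """
    if velocities is None:
        v = traj.require_velocities()[:, atom_index, :]
        dt = traj.timestep
    else:
        v = np.asarray(velocities, dtype=float)
        if dt is None:
            raise ValueError("dt is required with a raw velocity series")
    n = v.shape[0]

    spectra: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for nb in block_counts:
        blen = n // nb
        if blen < 2:
            raise ValueError(f"{nb} blocks would leave blocks of <2 frames")
        max_lag = blen - 1
        acc = None
        for b in range(nb):
            seg = v[b * blen : (b + 1) * blen]
            acf = np.zeros(max_lag + 1)
            for d in range(3):
                acf += _autocorr_fft(seg[:, d], max_lag)
            acc = acf if acc is None else acc + acf
        acf = acc / nb
        if window == "hann":
            acf = acf * np.hanning(2 * len(acf) - 1)[len(acf) - 1 :]
        intensity = np.abs(np.fft.rfft(acf))
        freq = np.fft.rfftfreq(len(acf), d=dt)
        spectra[nb] = (freq, intensity)

    peaks = {nb: _lowest_interior_peak(f, s) for nb, (f, s) in spectra.items()}
    # average over block counts on the finest grid
    finest = min(block_counts, key=lambda nb: spectra[nb][0][1] if len(spectra[nb][0]) > 1 else np.inf)
    f_ref = spectra[finest][0]
    avg = np.zeros_like(f_ref)
    for nb in block_counts:
        f, s = spectra[nb]
        avg += np.interp(f_ref, f, s)
    avg /= len(block_counts)
    return VDOSResult(
        freq_fs=f_ref,
        intensity=avg,
        block_counts=tuple(block_counts),
        peak_by_block_count=peaks,
    )


def _lowest_interior_peak(freq: np.ndarray, intensity: np.ndarray,
                          min_prominence_frac: float = 0.05) -> float | None:
    """Frequency of the lowest interior local maximum (zero bin excluded).

    Peaks must have a prominence of at least ``min_prominence_frac`` of the
    spectrum maximum, so low-frequency statistical ripple is not mistaken
    for the caged-ion band.
    """
    from scipy.signal import find_peaks

    if len(intensity) < 3:
        return None
    peaks, _ = find_peaks(intensity[1:], prominence=min_prominence_frac * intensity.max())
    if peaks.size == 0:
        return None
    return float(freq[peaks[0] + 1])


def rattling_period(result: VDOSResult) -> float:
    """Rattling period 1/nu from the lowest interior VDOS maximum (fs).

    The zero-frequency bin is excluded (drift/diffusion contaminate nu=0).
    Raises when the spectrum decays monotonically from zero, i.e. the ion
    shows no caged oscillation and a manual period must be supplied.
    """
    nu = _lowest_interior_peak(result.freq_fs, result.intensity)
    if nu is None or nu <= 0:
        raise ValueError(
            "VDOS has no interior maximum; no caged rattling motion detected "
            "- supply the rattling period manually"
        )
    result.rattling_freq = nu
    result.rattling_period = 1.0 / nu
    return result.rattling_period
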