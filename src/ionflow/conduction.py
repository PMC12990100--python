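"""Ionic current density and finite-field conductivity.

The instantaneous ionic current density along the field (z) axis is built
from the ion's atomic polar tensor and velocity,

    J_ion,z(t) = (1/V) sum_eta P_ion,eta,z * v_ion,eta(t),

in internal units e A^-2 fs^-1 (multiply by ``constants.CURRENT_SI`` for
A m^-2).  Stage means carry block-averaged standard errors (block length
grown by doubling until the blocked SEM plateaus, to absorb the
statistical inefficiency of correlated series).  The conductivity is the
slope of a weighted zero-intercept regression of <J> on the field inside
the linear regime; dividing by the cation concentration gives the molar
conductivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, CONDUCTIVITY_SI, CURRENT_SI, WATER_MOLAR_MASS
from .trajectory import Trajectory

__all__ = [
    "CurrentDensitySeries",
    "ConductivityFit",
    "current_density_series",
    "mean_with_blocked_sem",
    "conductivity_fit",
    "concentration_from_box",
    "water_box_volume",
    "molar_conductivity",
    "LINEAR_CUTOFF_DEFAULT",
]

LINEAR_CUTOFF_DEFAULT = 0.0514  # V/A
DISCARD_DEFAULT_FS = 20_000.0


@dataclass
class CurrentDensitySeries:
    j: np.ndarray  # e A^-2 fs^-1, per retained frame
    times: np.ndarray  # fs
    volume: float  # A^3
    stage: int | None = None

    @property
    def j_si(self) -> np.ndarray:
        return self.j * CURRENT_SI


@dataclass
class ConductivityFit:
    fields: np.ndarray  # V/A, points used in the fit
    means: np.ndarray  # e A^-2 fs^-1
    sems: np.ndarray
    linear_cutoff: float
    sigma: float  # S/m
    sigma_se: float  # S/m
    r_squared: float
    molar_conductivity: float | None = None  # S cm^2/mol
    concentration: float | None = None  # mol/L


def current_density_series(
    traj: Trajectory,
    ion_apt: np.ndarray,
    volume: float | None = None,
    ion_index: int = 0,
    frame_apts: np.ndarray | None = None,
) -> CurrentDensitySeries:
    """Per-frame J_z from the ion APT's z-column and the ion velocity.

    The APT is the static table tensor by default; ``frame_apts`` accepts a
    per-frame (n_frames, 3, 3) series when one is available.
    """
    v = traj.require_velocities()[:, ion_index, :]
    if volume is None:
        volume = traj.box_length**3
    if volume <= 0:
        raise ValueError("cell volume must be positive")
    if frame_apts is not None:
        col = np.asarray(frame_apts, dtype=float)[:, :, 2]
        j = np.einsum("te,te->t", col, v) / volume
    else:
        col = np.asarray(ion_apt, dtype=float)[:, 2]  # P_{ion,eta,z}
        j = v @ col / volume
    return CurrentDensitySeries(j=j, times=traj.times.copy(), volume=float(volume))


def mean_with_blocked_sem(
    series: CurrentDensitySeries | np.ndarray,
    discard_fs: float = 0.0,
    times: np.ndarray | None = None,
    plateau_rtol: float = 0.05,
    min_blocks: int = 8,
) -> tuple[float, float]:
    """Stage mean with a block-averaged standard error.

    Leading frames inside ``discard_fs`` are dropped.  Block length starts
    at 1 frame and doubles; the SEM of block means (ddof=1, divided by
    sqrt(n_blocks)) is accepted once it changes by less than
    ``plateau_rtol`` over two successive doublings.  If no plateau is
    reached before fewer than ``min_blocks`` blocks remain, the
    largest-block SEM is returned with a warning.
    """
    if isinstance(series, CurrentDensitySeries):
        x, t = series.j, series.times
    else:
        x = np.asarray(series, dtype=float)
        t = np.arange(len(x)) if times is None else np.asarray(times, dtype=float)
    if discard_fs > 0:
        keep = t >= t[0] + discard_fs
        x = x[keep]
    if x.size < 2:
        raise ValueError("series too short after discard")
    mean = float(x.mean())
    if np.ptp(x) == 0.0:
        return mean, 0.0

    sems = []
    blen = 1
    while x.size // blen >= min_blocks:
        nb = x.size // blen
        bm = x[: nb * blen].reshape(nb, blen).mean(axis=1)
        sems.append(float(bm.std(ddof=1) / np.sqrt(nb)))
        if len(sems) >= 3:
            a, b, c = sems[-3], sems[-2], sems[-1]
            if abs(c - b) < plateau_rtol * c and abs(b - a) < plateau_rtol * c:
                return mean, c
        blen *= 2
    warnings.warn(
        "blocked SEM did not plateau before running out of blocks; "
        "reporting the largest-block estimate",
        stacklevel=2,
    )
    return mean, sems[-1]


def conductivity_fit(
    fields,
    means,
    sems,
    linear_cutoff: float = LINEAR_CUTOFF_DEFAULT,
) -> ConductivityFit:
    """Weighted zero-intercept regression <J> = sigma E inside the linear regime.

    ``fields`` in V/A, ``means``/``sems`` in e A^-2 fs^-1.  Weights are
    1/SEM^2 (relative only: jointly rescaling all SEMs leaves the slope
    unchanged); equal weights are used when any SEM is zero.  The slope is
    converted to S/m.
    """
    fields = np.asarray(fields, dtype=float)
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    sel = fields <= linear_cutoff + 1e-12
    if not np.any(sel):
        raise ValueError(
            f"no field points at or below the linear cutoff {linear_cutoff} V/A"
        )
    E, J, S = fields[sel], means[sel], sems[sel]
    w = 1.0 / S**2 if np.all(S > 0) else np.ones_like(E)
    swe2 = float((w * E * E).sum())
    slope = float((w * E * J).sum()) / swe2
    slope_var = 1.0 / swe2 if np.all(S > 0) else np.nan
    resid = J - slope * E
    tss = float((w * J * J).sum())
    r2 = 1.0 - float((w * resid * resid).sum()) / tss if tss > 0 else np.nan
    return ConductivityFit(
        fields=E,
        means=J,
        sems=S,
        linear_cutoff=linear_cutoff,
        sigma=slope * CONDUCTIVITY_SI,
        sigma_se=float(np.sqrt(slope_var)) * CONDUCTIVITY_SI if np.isfinite(slope_var) else np.nan,
        r_squared=r2,
    )


def water_box_volume(n_waters: int, density_kg_per_l: float = 0.99659) -> float:
    """Volume (A^3) of a box of ``n_waters`` water molecules at the given density."""
    mass_g = n_waters * WATER_MOLAR_MASS / AVOGADRO
    volume_cm3 = mass_g / density_kg_per_l  # 1 kg/L == 1 g/cm^3
    return volume_cm3 * 1e24


def concentration_from_box(n_ions: int, volume_a3: float) -> float:
    """Nominal molarity of ``n_ions`` ions in a periodic cell of the given volume."""
    if volume_a3 <= 0:
        raise ValueError("volume must be positive")
    volume_l = volume_a3 * 1e-27
    return n_ions / (AVOGADRO * volume_l)


def molar_conductivity(sigma_s_per_m: float, concentration_mol_per_l: float) -> float:
    """Lambda_m = sigma / c in S cm^2 mol^-1 (sigma in S/m, c in mol/L)."""
    if concentration_mol_per_l <= 0:
        raise ValueError("ion concentration must be positive")
    c_si = concentration_mol_per_l * 1000.0  # mol/m^3
    return sigma_s_per_m / c_si * 1e4
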