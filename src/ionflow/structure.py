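"""Static solvation-structure analyses.

Ion-solvent radial distribution function with running coordination number,
detection of the first-shell radius R0 (first minimum of a smoothed g(r)
after the first peak), the rational switching-function coordination number

    CN = sum_j (1 - (r_j/R0)^NN) / (1 - (r_j/R0)^ND),   NN = 20, ND = 40,

the potential of mean force along CN, integer-CN histograms, and the joint
(cos alpha, cos theta) tilt-angle density of first-shell solvent dipoles,
where theta is the dipole tilt against the field direction and alpha the
angle between the shell-member -> ion vector and the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .constants import KB_EV
from .trajectory import Trajectory, minimum_image_displacement

__all__ = [
    "RDFResult",
    "ShellSeries",
    "PMFResult",
    "TiltAngleDensity",
    "compute_rdf",
    "detect_first_minimum",
    "smooth_cn",
    "shell_series",
    "pmf_from_cn_series",
    "integer_cn_histogram",
    "tilt_angle_density",
    "cos_to_degrees",
]

DEFAULT_BIN_WIDTH = 0.03  # A
NN_DEFAULT = 20
ND_DEFAULT = 40


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, A
    g: np.ndarray
    running_cn: np.ndarray  # n(r)
    density: float  # bulk partner number density, A^-3
    bin_width: float
    n_frames: int
    r0: float | None = None  # detected first-shell radius


@dataclass
class ShellSeries:
    """Per-frame first-shell membership backbone.

    ``members[t]`` is the frozenset of partner-atom ids inside R0 at frame
    ``t``; ``cn`` the integer coordination numbers (== member-set sizes);
    ``smooth_cn`` the switching-function CN when distances were available.
    """

    members: list
    cn: np.ndarray
    dt: float
    r0: float | None = None
    smooth_cn: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=int)
        if len(self.members) != len(self.cn):
            raise ValueError("members/cn length mismatch")
        for t, m in enumerate(self.members):
            if len(m) != self.cn[t]:
                raise ValueError(f"frame {t}: member-set size != integer CN")

    @property
    def n_frames(self) -> int:
        return len(self.members)


@dataclass
class PMFResult:
    cn_grid: np.ndarray
    pmf: np.ndarray  # in units of kB*T (NaN on empty bins)
    temperature: float
    bin_width: float
    counts: np.ndarray

    def in_kj_per_mol(self) -> np.ndarray:
        return self.pmf * KB_EV * self.temperature * 96.48533  # eV -> kJ/mol


@dataclass
class TiltAngleDensity:
    cos_alpha_edges: np.ndarray
    cos_theta_edges: np.ndarray
    density: np.ndarray  # normalized so that sum * cell-area == 1
    n_samples: int
    leading_mean_cos_theta: float  # cos(alpha) < 0 subset
    trailing_mean_cos_theta: float  # cos(alpha) > 0 subset
    correlation: float  # Pearson r between cos(alpha) and cos(theta)


def _ion_index(traj: Trajectory, center_species: str) -> int:
    idx = traj.atom_indices(center_species)
    if idx.size != 1:
        raise ValueError(
            f"expected exactly one {center_species!r} atom, found {idx.size}"
        )
    return int(idx[0])


def _ion_partner_distances(traj: Trajectory, center_species: str,
                           partner_species: str) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, n_partners) minimum-image ion-partner distances."""
    ion = _ion_index(traj, center_species)
    partners = traj.atom_indices(partner_species)
    if partners.size == 0:
        raise ValueError(f"no atoms of partner species {partner_species!r}")
    d = minimum_image_displacement(
        traj.positions[:, ion, None, :], traj.positions[:, partners, :], traj.box_length
    )
    return np.linalg.norm(d, axis=-1), partners


def compute_rdf(
    traj: Trajectory,
    center_species: str = "ION",
    partner_species: str = "SOL",
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
    discard_fs: float = 0.0,
) -> RDFResult:
    """Ion-partner g(r) and running coordination number n(r).

    Standard pair normalization: counts per bin divided by frame count,
    shell volume and the bulk partner density N_partner / V.  ``n(r)`` is
    the cumulative raw count per frame, i.e. 4 pi rho int g s^2 ds on the
    same binning.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if discard_fs > 0:
        traj = traj.slice_frames(traj.times >= traj.times[0] + discard_fs)
    if traj.n_frames < 1:
        raise ValueError("no frames left after discard")
    if r_max is None:
        r_max = traj.box_length / 2.0
    dists, partners = _ion_partner_distances(traj, center_species, partner_species)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(dists.ravel(), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = partners.size / traj.box_length**3
    shell_vol = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (traj.n_frames * shell_vol * rho)
    running = np.cumsum(counts) / traj.n_frames
    return RDFResult(
        r=centers, g=g, running_cn=running, density=rho,
        bin_width=bin_width, n_frames=traj.n_frames,
    )


def detect_first_minimum(
    rdf: RDFResult,
    smooth_window: int = 11,
    smooth_order: int = 3,
    search_factor: float = 1.8,
) -> float:
    """First-shell radius R0: first local minimum of smoothed g(r) after its
    first peak, searched out to ``search_factor`` times the peak position.

    Raises ValueError when no interior minimum exists (e.g. monotone g(r)
    or a shell so flat that no valley survives smoothing), in which case a
    manual cutoff has to be supplied.
    """
    g = rdf.g
    if len(g) >= smooth_window:
        g = savgol_filter(g, smooth_window, smooth_order)
    # first peak: first index that is a strict local maximum with g > 0.5
    peak = None
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0.5:
            peak = i
            break
    if peak is None:
        raise ValueError("g(r) has no first peak; cannot detect a first minimum")
    r_peak = rdf.r[peak]
    stop = int(np.searchsorted(rdf.r, search_factor * r_peak))
    for i in range(peak + 1, min(stop, len(g) - 1)):
        if g[i] < g[i - 1] and g[i] <= g[i + 1]:
            rdf.r0 = float(rdf.r[i])
            return rdf.r0
    raise ValueError(
        "no local minimum of g(r) found after the first peak; "
        "supply the first-shell cutoff manually"
    )


def smooth_cn(distances, r0: float, nn: int = NN_DEFAULT, nd: int = ND_DEFAULT) -> float:
    """Switching-function coordination number.

    Each distance contributes (1 - x^NN)/(1 - x^ND) with x = r/R0.  For the
    default ND = 2*NN this reduces algebraically to 1/(1 + x^NN), which also
    supplies the x = 1 limit NN/ND = 1/2 without special-casing.
    """
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    x = np.asarray(distances, dtype=float) / r0
    if nd == 2 * nn:
        terms = 1.0 / (1.0 + x**nn)
    else:
        num, den = 1.0 - x**nn, 1.0 - x**nd
        terms = np.where(np.abs(den) < 1e-12, nn / nd, num / np.where(den == 0, 1.0, den))
    return float(np.sum(terms))


def shell_series(
    traj: Trajectory,
    r0: float,
    center_species: str = "ION",
    partner_species: str = "SOL",
    nn: int = NN_DEFAULT,
    nd: int = ND_DEFAULT,
    discard_fs: float = 0.0,
) -> ShellSeries:
    """Per-frame first-shell membership, integer CN and smooth CN.

    Membership uses strict inequality r < R0 (ties at exactly R0 excluded).
    """
    if discard_fs > 0:
        traj = traj.slice_frames(traj.times >= traj.times[0] + discard_fs)
    dists, partners = _ion_partner_distances(traj, center_species, partner_species)
    x = dists / r0
    if nd == 2 * nn:
        sw = 1.0 / (1.0 + x**nn)
    else:
        sw = (1.0 - x**nn) / (1.0 - x**nd)
    smooth = sw.sum(axis=1)
    inside = dists < r0
    members = [frozenset(partners[row].tolist()) for row in inside]
    cn = inside.sum(axis=1)
    return ShellSeries(
        members=members, cn=cn, dt=traj.timestep, r0=r0, smooth_cn=smooth
    )


def pmf_from_cn_series(
    cn_values,
    temperature: float = 300.0,
    bin_width: float = 0.1,
) -> PMFResult:
    """Potential of mean force along CN: -kB T ln p(CN), minimum pinned to 0.

    Returned in units of kB*T; empty bins are NaN (undefined), never zero.
    """
    cn_values = np.asarray(cn_values, dtype=float)
    if cn_values.size == 0:
        raise ValueError("empty CN series")
    import warnings

    if cn_values.size < 100:
        warnings.warn("fewer than 100 CN samples; PMF will be noisy", stacklevel=2)
    lo = np.floor(cn_values.min() / bin_width) * bin_width
    hi = np.ceil(cn_values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
        warnings.warn("all CN samples identical; single-point PMF", stacklevel=2)
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(cn_values, bins=edges)
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        pmf = -np.log(p)
    pmf[counts == 0] = np.nan
    pmf -= np.nanmin(pmf)
    return PMFResult(
        cn_grid=0.5 * (edges[:-1] + edges[1:]),
        pmf=pmf,
        temperature=temperature,
        bin_width=bin_width,
        counts=counts,
    )


def integer_cn_histogram(shell: ShellSeries) -> dict[int, int]:
    """Counts per integer coordination number; values sum to the frame count."""
    vals, counts = np.unique(shell.cn, return_counts=True) if shell.n_frames else ((), ())
    return {int(v): int(c) for v, c in zip(vals, counts)}


def tilt_angle_density(
    traj: Trajectory,
    shell: ShellSeries,
    field_direction,
    bins: int = 40,
    center_species: str = "ION",
) -> TiltAngleDensity:
    """Joint density of (cos alpha, cos theta) conditional on shell membership.

    cos alpha = unit(r_ion - r_member) . e_hat (member->ion axis against the
    field; trailing members have cos alpha > 0, leading ones < 0) and
    cos theta = dipole . e_hat.  The histogram is normalized to integrate
    to 1 over [-1, 1]^2.
    """
    if traj.dipoles is None:
        raise ValueError("tilt-angle analysis requires dipole orientations")
    e = np.asarray(field_direction, dtype=float)
    norm = np.linalg.norm(e)
    if norm == 0:
        raise ValueError(
            "field direction is zero; supply a reference axis for zero-field analyses"
        )
    e = e / norm
    ion = _ion_index(traj, center_species)
    if shell.n_frames != traj.n_frames:
        raise ValueError("shell series and trajectory are not frame-aligned")

    cos_a_all, cos_t_all = [], []
    for t in range(traj.n_frames):
        mem = np.fromiter(shell.members[t], dtype=int, count=len(shell.members[t]))
        if mem.size == 0:
            continue
        d = minimum_image_displacement(
            traj.positions[t, mem, :], traj.positions[t, ion, :], traj.box_length
        )
        r = np.linalg.norm(d, axis=-1)
        cos_a_all.append((d @ e) / r)
        cos_t_all.append(traj.dipoles[t, mem, :] @ e)
    if not cos_a_all:
        raise ValueError("no first-shell occupancy anywhere in the trajectory")
    cos_a = np.concatenate(cos_a_all)
    cos_t = np.concatenate(cos_t_all)

    edges = np.linspace(-1.0, 1.0, bins + 1)
    hist, _, _ = np.histogram2d(cos_a, cos_t, bins=(edges, edges))
    cell = (2.0 / bins) ** 2
    density = hist / (hist.sum() * cell)

    leading = cos_t[cos_a < 0]
    trailing = cos_t[cos_a > 0]
    if cos_a.size > 2 and cos_a.std() > 0 and cos_t.std() > 0:
        corr = float(np.corrcoef(cos_a, cos_t)[0, 1])
    else:
        corr = np.nan
    return TiltAngleDensity(
        cos_alpha_edges=edges,
        cos_theta_edges=edges,
        density=density,
        n_samples=int(cos_a.size),
        leading_mean_cos_theta=float(leading.mean()) if leading.size else np.nan,
        trailing_mean_cos_theta=float(trailing.mean()) if trailing.size else np.nan,
        correlation=corr,
    )


def cos_to_degrees(cos_value: float) -> float:
    """Convert a mean cosine to the corresponding tilt angle in degrees."""
    return float(np.degrees(np.arccos(cos_value)))
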