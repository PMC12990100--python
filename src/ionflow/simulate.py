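"""Toy finite-field electrolyte: Langevin dynamics of one cation in a
dipolar solvent bath, plus a stochastic coordination-state generator.

The simulator reproduces the statistical structure the transport analyses
assume -- distinct, exchangeable first solvation shells whose stability is
set by the ion-solvent well depth, solvent dipoles that align with an
external field, and steady-state ion drift with Joule heat removed by the
Langevin friction -- without any electronic-structure machinery.  Solvent
particles are single Lennard-Jones sites carrying a rigid point dipole
evolved by overdamped rotational Langevin dynamics; translations use BAOAB
velocity-Verlet Langevin splitting.  The field acts on translations
through the field-coupling module (ion polar tensor q*I, solvent tensors
zero) and on rotations through the dipole torque.

Ion presets ("li", "na", "cs") differ in mass, contact distance and the
ion-solvent well-depth multiplier, giving strongly bound, intermediate and
labile first shells respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .constants import AMU_TO_INTERNAL, COULOMB_EV_A, KB_EV
from .field_coupling import (
    AtomicPolarTensorSet,
    FieldVector,
    perturbed_forces,
)
from .structure import ShellSeries
from .trajectory import Trajectory

__all__ = [
    "SimConfig",
    "FieldStage",
    "FieldProtocol",
    "ramp_protocol",
    "preset_config",
    "simulate",
    "IntegrationError",
    "MarkovCNParams",
    "MarkovCNSeries",
    "generate_markov_cn_series",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Parameters of the toy electrolyte (units: A, fs, eV, e, amu, K)."""

    n_solvent: int = 200
    box_length: float = 18.2
    ion_mass: float = 22.99  # amu
    solvent_mass: float = 18.015  # amu
    sigma_ss: float = 3.0  # solvent-solvent LJ sigma, A
    eps_ss: float = 0.0067  # solvent-solvent LJ well depth, eV
    sigma_is: float = 2.25  # ion-solvent LJ sigma, A
    eps_is_base: float = 0.02  # eV; multiplied by ion_well_multiplier
    ion_well_multiplier: float = 2.5  # "Li-like" high, "Cs-like" low
    ion_born_charge: float = 1.0  # e
    dipole_moment: float = 0.385  # e A (water-like 1.85 D)
    trans_friction: float = 0.01  # fs^-1
    rot_diffusion: float = 0.002  # fs^-1 rotational diffusion constant
    temperature: float = 300.0  # K
    timestep: float = 1.0  # fs
    seed: int = 0
    sample_every: int = 5  # store every n-th step
    coulomb_cutoff: float = 8.0  # A, ion charge-dipole field cutoff
    vmax: float = 0.5  # A/fs blow-up guard
    init_min_dist_factor: float = 0.80  # min insert distance in units of sigma
    max_init_attempts: int = 500  # per particle

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        largest_cut = max(2.5 * self.sigma_ss, 2.5 * self.sigma_is, self.coulomb_cutoff)
        if self.box_length <= 2.0 * largest_cut and self.n_solvent > 0:
            raise ValueError(
                f"box length {self.box_length} must exceed twice the largest "
                f"interaction cutoff ({largest_cut:.2f} A)"
            )

    @property
    def kT(self) -> float:
        return KB_EV * self.temperature

    @property
    def n_atoms(self) -> int:
        return 1 + self.n_solvent

    @property
    def species(self) -> list[str]:
        return ["ION"] + ["SOL"] * self.n_solvent

    def ion_apts(self) -> AtomicPolarTensorSet:
        """Per-atom polar tensors of the toy: q*I on the ion, zero on solvent."""
        tensors = np.zeros((self.n_atoms, 3, 3))
        tensors[0] = self.ion_born_charge * np.eye(3)
        return AtomicPolarTensorSet(
            tensors=tensors, q_tot=self.ion_born_charge, species=self.species
        )


#: preset ion-solvent channels: (mass amu, sigma_is A, well multiplier)
#: the well-depth multiplier is the shell-stability dial: high -> strongly
#: bound, low-CN shell ("Li-like"), low -> labile shell ("Cs-like")
PRESETS = {
    "li": (6.94, 1.85, 12.0),
    "na": (22.99, 2.25, 2.5),
    "cs": (132.91, 2.25, 0.4),
}


def preset_config(kind: str, **overrides) -> SimConfig:
    """SimConfig for a 'li'/'na'/'cs'-like cation (shell stability high/mid/low)."""
    mass, sigma_is, mult = PRESETS[kind.lower()]
    cfg = SimConfig(ion_mass=mass, sigma_is=sigma_is, ion_well_multiplier=mult)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class FieldStage:
    field: FieldVector
    duration_fs: float
    discard_fs: float = 0.0

    def __post_init__(self) -> None:
        if not (self.duration_fs > self.discard_fs >= 0):
            raise ValueError("stage needs duration > discard >= 0")


@dataclass
class FieldProtocol:
    stages: list[FieldStage]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")

    @property
    def total_duration(self) -> float:
        return sum(s.duration_fs for s in self.stages)

    def magnitudes(self) -> np.ndarray:
        return np.array([s.field.magnitude for s in self.stages])

    @classmethod
    def single(cls, field: FieldVector, duration_fs: float, discard_fs: float = 0.0):
        return cls([FieldStage(field, duration_fs, discard_fs)])

    @classmethod
    def zero_field(cls, duration_fs: float, discard_fs: float = 0.0):
        return cls.single(FieldVector((0.0, 0.0, 0.0)), duration_fs, discard_fs)


def ramp_protocol(
    paper_preset: bool = True,
    duration_fs: float = 200_000.0,
    discard_fs: float = 20_000.0,
    magnitudes: Sequence[float] | None = None,
) -> FieldProtocol:
    """Stepped field ramp along z.

    With ``paper_preset`` the 21 stage magnitudes follow the published
    protocol: 2.57e-3 .. 2.57e-2 V/A in steps of 2.57e-3, then up to
    5.14e-2 in steps of 5.14e-3, then up to 2.06e-1 in steps of 2.57e-2.
    """
    if magnitudes is None:
        if not paper_preset:
            raise ValueError("supply explicit magnitudes when paper_preset is off")
        base = 2.57e-3
        mags = [k * base for k in range(1, 11)]  # to 2.57e-2
        mags += [2.57e-2 + k * 5.14e-3 for k in range(1, 6)]  # to 5.14e-2
        mags += [5.14e-2 + k * 2.57e-2 for k in range(1, 7)]  # to 2.056e-1
        magnitudes = mags
    stages = [
        FieldStage(FieldVector.along_z(m), duration_fs, discard_fs) for m in magnitudes
    ]
    return FieldProtocol(stages)


# -- initial conditions --------------------------------------------------

def _initial_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random sequential insertion with overlap rejection (bounded attempts)."""
    n = cfg.n_atoms
    pos = np.empty((n, 3))
    pos[0] = cfg.box_length / 2.0
    min_d2 = np.empty(n)
    for i in range(1, n):
        d_ion = cfg.init_min_dist_factor * cfg.sigma_is
        d_sol = cfg.init_min_dist_factor * cfg.sigma_ss
        placed = False
        for _ in range(cfg.max_init_attempts):
            trial = rng.random(3) * cfg.box_length
            d = pos[:i] - trial
            d -= cfg.box_length * np.round(d / cfg.box_length)
            r = np.sqrt((d * d).sum(axis=1))
            if r[0] >= d_ion and (i == 1 or np.all(r[1:] >= d_sol)):
                pos[i] = trial
                placed = True
                break
        if not placed:
            raise IntegrationError(
                f"could not place particle {i} without overlap after "
                f"{cfg.max_init_attempts} jittered attempts; lower the density"
            )
    return pos


def _initial_velocities(cfg: SimConfig, masses: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal((cfg.n_atoms, 3)) * np.sqrt(cfg.kT / masses[:, None])


def _initial_dipoles(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    u = rng.standard_normal((cfg.n_atoms, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u[0] = 0.0  # the ion carries no dipole
    return u


# -- main driver ---------------------------------------------------------

def simulate(
    config: SimConfig,
    protocol: FieldProtocol,
    store: str = "all",
) -> Trajectory:
    """Run the field protocol and return the sampled trajectory.

    ``store="all"`` keeps every atom; ``store="ion"`` keeps only the cation
    (positions/velocities), which is all the conduction and diffusion
    analyses need and keeps long runs cheap.  Samples are taken every
    ``config.sample_every`` steps; stage boundaries are rounded to a whole
    number of sampling intervals so the global time grid stays uniform.
    Per-stage mean kinetic temperatures (after each stage's discard) are
    recorded in ``metadata["stage_temperatures"]``.
    """
    if store not in ("all", "ion"):
        raise ValueError("store must be 'all' or 'ion'")
    store_all = store == "all"
    dt = config.timestep
    se = config.sample_every

    masses = np.full(config.n_atoms, config.solvent_mass * AMU_TO_INTERNAL)
    masses[0] = config.ion_mass * AMU_TO_INTERNAL

    ss = np.random.SeedSequence(config.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    stage_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(protocol.stages))]

    pos = _initial_positions(config, init_rng)
    vel = _initial_velocities(config, masses, init_rng)
    uvec = _initial_dipoles(config, init_rng)

    apts = config.ion_apts()
    n_store = 1 if not store_all else config.n_atoms

    all_pos, all_vel, all_dip, all_t, all_field, all_stage = [], [], [], [], [], []
    stage_temps = []
    t_now = 0.0
    for k, stage in enumerate(protocol.stages):
        n_steps = max(se, int(round(stage.duration_fs / dt / se)) * se)
        n_discard = int(round(stage.discard_fs / dt))
        field_force = perturbed_forces(apts, stage.field).forces
        n_samples_max = n_steps // se
        out_pos = np.empty((n_samples_max, n_store, 3))
        out_vel = np.empty((n_samples_max, n_store, 3))
        out_dip = np.zeros((n_samples_max, n_store, 3))

        status, fail_step, n_samples, mean_T = _kernels.run_stage(
            pos, vel, uvec, masses, field_force, stage.field.array,
            config.box_length, dt, n_steps,
            config.trans_friction, config.rot_diffusion, config.kT,
            config.sigma_ss**2, config.eps_ss, (2.5 * config.sigma_ss) ** 2,
            config.sigma_is**2,
            config.eps_is_base * config.ion_well_multiplier,
            (2.5 * config.sigma_is) ** 2,
            config.ion_born_charge, config.dipole_moment,
            COULOMB_EV_A, config.coulomb_cutoff**2,
            se, store_all, n_discard, config.vmax, stage_seeds[k],
            out_pos, out_vel, out_dip,
        )
        if status != _kernels.STATUS_OK:
            raise IntegrationError(
                f"velocity blow-up in stage {k} at step {fail_step} "
                f"(|v| exceeded {config.vmax} A/fs)"
            )
        stage_temps.append(mean_T / KB_EV)  # kernel returns kB*T in eV
        all_pos.append(out_pos[:n_samples])
        all_vel.append(out_vel[:n_samples])
        all_dip.append(out_dip[:n_samples])
        all_t.append(t_now + dt * se * (1 + np.arange(n_samples)))
        all_field.append(np.tile(stage.field.array, (n_samples, 1)))
        all_stage.append(np.full(n_samples, k, dtype=int))
        t_now += n_steps * dt

    species = config.species if store_all else ["ION"]
    return Trajectory(
        times=np.concatenate(all_t),
        box_length=config.box_length,
        species=species,
        positions=np.concatenate(all_pos),
        velocities=np.concatenate(all_vel),
        dipoles=np.concatenate(all_dip) if store_all else None,
        fields=np.concatenate(all_field),
        stage_ids=np.concatenate(all_stage),
        metadata={
            "seed": config.seed,
            "stage_seeds": stage_seeds,
            "stage_temperatures": stage_temps,
            "timestep": dt * se,
            "sample_every": se,
            "config": config,
            "protocol": protocol,
        },
    )


def stage_frames(traj: Trajectory, stage: int, drop_discard: bool = True) -> np.ndarray:
    """Boolean frame mask for one protocol stage, optionally after its discard."""
    proto: FieldProtocol = traj.metadata["protocol"]
    mask = traj.stage_ids == stage
    if drop_discard:
        t0 = traj.times[mask][0]
        mask &= traj.times >= t0 + proto.stages[stage].discard_fs
    return mask


# -- Markov coordination-state generator ---------------------------------

@dataclass
class MarkovCNParams:
    """Exact-oracle generator of piecewise-constant shell membership.

    The integer CN performs a continuous-time Markov walk over
    ``cn_states`` (exponential dwell with per-state ``exit_rates``, jumps
    to a uniformly chosen neighbouring state).  Independently, each shell
    member is swapped for a fresh one at ``swap_rate`` (identity change at
    constant CN).  Per-frame scalar drift velocity is Gaussian around the
    current state's ``drift_means``.
    """

    n_frames: int
    dt: float = 1.0  # fs
    cn_states: tuple[int, ...] = (4,)
    exit_rates: tuple[float, ...] = (0.0,)  # fs^-1, rate of leaving each state
    swap_rate: float = 0.0  # fs^-1 per member
    drift_means: tuple[float, ...] = (0.0,)
    drift_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if len(self.exit_rates) != len(self.cn_states) or len(self.drift_means) != len(self.cn_states):
            raise ValueError("per-state parameter lengths must match cn_states")
        if any(r < 0 for r in self.exit_rates) or self.swap_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class MarkovCNSeries:
    states: np.ndarray  # per-frame index into params.cn_states
    cn: np.ndarray
    members: list
    drift: np.ndarray  # per-frame scalar drift velocity
    params: MarkovCNParams
    seed: int

    def shell_series(self) -> ShellSeries:
        return ShellSeries(members=self.members, cn=self.cn, dt=self.params.dt)


def generate_markov_cn_series(params: MarkovCNParams, seed: int = 0) -> MarkovCNSeries:
    rng = np.random.default_rng(seed)
    n_states = len(params.cn_states)
    dt = params.dt

    # state path with exponential dwell times (>= 1 frame)
    states = np.empty(params.n_frames, dtype=int)
    t = 0
    s = 0
    while t < params.n_frames:
        rate = params.exit_rates[s]
        if rate > 0 and n_states > 1:
            dwell = max(1, int(np.ceil(rng.exponential(1.0 / rate) / dt)))
        else:
            dwell = params.n_frames - t
        end = min(params.n_frames, t + dwell)
        states[t:end] = s
        t = end
        if t < params.n_frames:
            neighbours = [j for j in (s - 1, s + 1) if 0 <= j < n_states]
            s = int(rng.choice(neighbours))

    cn_of = np.array(params.cn_states)
    cn = cn_of[states]

    # member identities
    members: list = []
    next_id = 0
    current: set[int] = set()
    p_swap = 1.0 - np.exp(-params.swap_rate * dt) if params.swap_rate > 0 else 0.0
    for t in range(params.n_frames):
        target = int(cn[t])
        while len(current) < target:
            current.add(next_id)
            next_id += 1
        while len(current) > target:
            current.remove(rng.choice(sorted(current)))
        if p_swap > 0 and current:
            for m in sorted(current):
                if rng.random() < p_swap:
                    current.remove(m)
                    current.add(next_id)
                    next_id += 1
        members.append(frozenset(current))

    drift_of = np.array(params.drift_means)
    drift = drift_of[states]
    if params.drift_noise > 0:
        drift = drift + params.drift_noise * rng.standard_normal(params.n_frames)
    return MarkovCNSeries(states=states, cn=cn, members=members, drift=drift,
                          params=params, seed=seed)
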