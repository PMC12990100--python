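"""Numba kernels for the toy finite-field electrolyte simulator.

Layout conventions: atom 0 is the cation, atoms 1..N are solvent.
Positions are unwrapped; the minimum-image convention is applied inside
the force loop, so coordinates never need wrapping.  All quantities are
in the package's internal units (A, fs, eV, e; masses in eV fs^2/A^2).
"""

import numba as nb
import numpy as np

STATUS_OK = 0
STATUS_BLOWUP = 1


@nb.njit(cache=True, fastmath=True)
def pair_forces(pos, box, sig2_ss, eps_ss, cut2_ss, sig2_is, eps_is, cut2_is, forces):
    """Truncated Lennard-Jones forces; atom 0 uses the ion-solvent channel."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if i == 0:
                sig2, eps, cut2 = sig2_is, eps_is, cut2_is
            else:
                sig2, eps, cut2 = sig2_ss, eps_ss, cut2_ss
            if r2 >= cut2 or r2 <= 1e-12:
                continue
            s2 = sig2 / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            # dU/dr / r with U = 4 eps (s12 - s6)
            fr = 24.0 * eps * (2.0 * s12 - s6) / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz


@nb.njit(cache=True, fastmath=True)
def _rotate_dipoles(pos, uvec, box, efield, q_ion, mu_dip, coul_k, coul_cut2,
                    rot_diff, kT, dt):
    """Overdamped rotational Langevin step on the solvent dipole unit vectors.

    Drift (D_r/kT) * torque with torque = mu * u x E_local; the local field is
    the external field plus the (cutoff) Coulomb field of the ion.  Stationary
    distribution is Boltzmann in -mu u.E_local.
    """
    n = pos.shape[0]
    drift_c = rot_diff / kT * dt
    noise_c = np.sqrt(2.0 * rot_diff * dt)
    for i in range(1, n):
        ex, ey, ez = efield[0], efield[1], efield[2]
        dx = pos[i, 0] - pos[0, 0]
        dy = pos[i, 1] - pos[0, 1]
        dz = pos[i, 2] - pos[0, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < coul_cut2 and r2 > 1e-12:
            r = np.sqrt(r2)
            pref = coul_k * q_ion / (r2 * r)
            ex += pref * dx
            ey += pref * dy
            ez += pref * dz
        ux, uy, uz = uvec[i, 0], uvec[i, 1], uvec[i, 2]
        # torque T = mu u x E
        tx = mu_dip * (uy * ez - uz * ey)
        ty = mu_dip * (uz * ex - ux * ez)
        tz = mu_dip * (ux * ey - uy * ex)
        ox = drift_c * tx + noise_c * np.random.normal(0.0, 1.0)
        oy = drift_c * ty + noise_c * np.random.normal(0.0, 1.0)
        oz = drift_c * tz + noise_c * np.random.normal(0.0, 1.0)
        # u <- u + dOmega x u, renormalized
        nx = ux + oy * uz - oz * uy
        ny = uy + oz * ux - ox * uz
        nz = uz + ox * uy - oy * ux
        inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
        uvec[i, 0] = nx * inv
        uvec[i, 1] = ny * inv
        uvec[i, 2] = nz * inv


@nb.njit(cache=True)
def run_stage(pos, vel, uvec, mass, field_force, efield,
              box, dt, n_steps,
              gamma_t, rot_diff, kT,
              sig2_ss, eps_ss, cut2_ss, sig2_is, eps_is, cut2_is,
              q_ion, mu_dip, coul_k, coul_cut2,
              sample_every, store_all, n_discard_steps, vmax, seed,
              out_pos, out_vel, out_dip):
    """BAOAB Langevin integration of one field-protocol stage.

    Samples state every ``sample_every`` steps (at steps sample_every,
    2*sample_every, ...).  Returns (status, fail_step, n_samples,
    mean_kinetic_temperature) where the temperature average runs over
    steps after ``n_discard_steps``.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    half_dt = 0.5 * dt
    c1 = np.exp(-gamma_t * dt)
    c2 = np.empty(n)
    for i in range(n):
        c2[i] = np.sqrt(kT / mass[i] * (1.0 - c1 * c1))

    forces = np.empty((n, 3))
    pair_forces(pos, box, sig2_ss, eps_ss, cut2_ss, sig2_is, eps_is, cut2_is, forces)
    for i in range(n):
        for d in range(3):
            forces[i, d] += field_force[i, d]

    n_samples = 0
    ke_sum = 0.0
    ke_count = 0
    vmax2 = vmax * vmax
    for step in range(n_steps):
        # B
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] / mass[i]
        # A
        for i in range(n):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        # O
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2[i] * np.random.normal(0.0, 1.0)
        # A
        for i in range(n):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        # force update + B
        pair_forces(pos, box, sig2_ss, eps_ss, cut2_ss, sig2_is, eps_is, cut2_is, forces)
        for i in range(n):
            for d in range(3):
                forces[i, d] += field_force[i, d]
                vel[i, d] += half_dt * forces[i, d] / mass[i]

        if mu_dip > 0.0 and n > 1:
            _rotate_dipoles(pos, uvec, box, efield, q_ion, mu_dip, coul_k,
                            coul_cut2, rot_diff, kT, dt)

        ke = 0.0
        for i in range(n):
            v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            if v2 > vmax2:
                return STATUS_BLOWUP, step, n_samples, 0.0
            ke += 0.5 * mass[i] * v2
        if step >= n_discard_steps:
            ke_sum += ke
            ke_count += 1

        if (step + 1) % sample_every == 0:
            if store_all:
                for i in range(n):
                    for d in range(3):
                        out_pos[n_samples, i, d] = pos[i, d]
                        out_vel[n_samples, i, d] = vel[i, d]
                        out_dip[n_samples, i, d] = uvec[i, d]
            else:
                for d in range(3):
                    out_pos[n_samples, 0, d] = pos[0, d]
                    out_vel[n_samples, 0, d] = vel[0, d]
            n_samples += 1

    mean_temp = 0.0
    if ke_count > 0:
        # kinetic temperature: <2 KE / (3 N kB)> with kB folded into kT units
        mean_temp = (2.0 * ke_sum / ke_count) / (3.0 * n)
    return STATUS_OK, -1, n_samples, mean_temp
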