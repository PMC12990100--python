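"""End-to-end study workflows on the toy electrolyte.

These drive the complete analyses the package exists for -- the
fluctuation-dissipation closure between the finite-field conductivity and
the zero-field Green-Kubo/Nernst-Einstein route, the per-preset shell
regime characterization (structure, lifetime, rattling period, vehicular/
structural breakdown), and the lifetime ordering across shell-stability
presets.  The acceptance tests, the acceptance script and the analysis
drivers all call these functions so every consumer runs the identical
computation.
"""

from __future__ import annotations

import numpy as np

from .constants import D_TO_SI
from .conduction import (
    concentration_from_box,
    conductivity_fit,
    current_density_series,
    mean_with_blocked_sem,
    molar_conductivity,
)
from .decomposition import classify_segments, decompose_current
from .dynamics import (
    bootstrap_diffusion,
    continuous_lifetime,
    green_kubo_D,
    nernst_einstein,
    rattling_period,
    survival_correlation,
    vacf,
    vdos,
)
from .simulate import (
    FieldProtocol,
    FieldStage,
    preset_config,
    simulate,
    stage_frames,
)
from .field_coupling import FieldVector
from .structure import (
    compute_rdf,
    detect_first_minimum,
    shell_series,
    tilt_angle_density,
)

__all__ = [
    "closure_experiment",
    "regime_experiment",
    "lifetime_ordering_experiment",
]

#: finite-field stage magnitudes used for conductivity fits (V/A), all
#: inside the linear-regime cutoff 0.0514 V/A
CLOSURE_FIELDS = (0.0103, 0.0206, 0.0308, 0.0411, 0.0514)


def green_kubo_lambda(
    velocities: np.ndarray,
    dt: float,
    temperature: float,
    concentration: float,
    segment_fs: float = 12_500.0,
    gk_limit_fs: float = 2500.0,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> dict:
    """Zero-field molar conductivity via segmented Green-Kubo + bootstrap.

    The ion velocity series is split into equal segments, a Green-Kubo D
    is estimated per segment (VACF integrated to ``gk_limit_fs``), and the
    segment estimates are bootstrap-resampled for the mean and its SD.
    """
    n = velocities.shape[0]
    seg_len = int(round(segment_fs / dt))
    n_seg = n // seg_len
    if n_seg < 2:
        raise ValueError("velocity series too short for segmented Green-Kubo")
    estimates = []
    for k in range(n_seg):
        seg = velocities[k * seg_len : (k + 1) * seg_len]
        res = vacf(None, velocities=seg, dt=dt, max_lag_fs=gk_limit_fs)
        estimates.append(green_kubo_D(res, gk_limit_fs))
    d_mean, d_sd = bootstrap_diffusion(estimates, n_resamples=n_resamples, seed=seed)
    lam = nernst_einstein(d_mean * D_TO_SI, temperature)
    lam_se = nernst_einstein(d_sd * D_TO_SI, temperature)
    return {
        "D_A2_per_fs": d_mean,
        "D_sd": d_sd,
        "n_segments": n_seg,
        "lambda_S_cm2_mol": lam,
        "lambda_se": lam_se,
        "estimates": estimates,
    }


def closure_experiment(
    seed: int = 1,
    preset: str = "na",
    n_solvent: int = 200,
    zero_duration_fs: float = 250_000.0,
    zero_discard_fs: float = 10_000.0,
    stage_duration_fs: float = 150_000.0,
    stage_discard_fs: float = 15_000.0,
    field_magnitudes=CLOSURE_FIELDS,
    sample_every: int = 2,
    n_resamples: int = 10_000,
    gk_limit_fs: float = 750.0,
) -> dict:
    """Fluctuation-dissipation closure on the toy electrolyte.

    Runs one zero-field trajectory (molar conductivity via Green-Kubo +
    Nernst-Einstein) and one stepped finite-field protocol (molar
    conductivity from the weighted zero-intercept fit of <J_z> against E_z
    in the linear regime), and reports both with their standard errors and
    the combined-SE agreement statistic.

    The Green-Kubo integration limit follows the method's own rule -- the
    VACF is integrated only out to where the integral has converged.  The
    toy ion's VACF has an integral timescale of ~30 fs, so the default
    limit of 0.75 ps (25 integral times) is fully converged; integrating
    further would only accumulate statistical noise.
    """
    cfg = preset_config(preset, seed=seed, n_solvent=n_solvent, sample_every=sample_every)
    conc = concentration_from_box(1, cfg.box_length**3)

    # zero-field route
    traj0 = simulate(cfg, FieldProtocol.zero_field(zero_duration_fs, zero_discard_fs), store="ion")
    keep = traj0.times >= traj0.times[0] + zero_discard_fs
    v0 = traj0.velocities[keep, 0, :]
    gk = green_kubo_lambda(
        v0, traj0.timestep, cfg.temperature, conc, n_resamples=n_resamples,
        seed=seed, gk_limit_fs=gk_limit_fs,
    )

    # finite-field route: sequentially stepped stages, each re-equilibrated
    stages = [
        FieldStage(FieldVector.along_z(m), stage_duration_fs, stage_discard_fs)
        for m in field_magnitudes
    ]
    cfg_ff = preset_config(preset, seed=seed + 1, n_solvent=n_solvent, sample_every=sample_every)
    traj_ff = simulate(cfg_ff, FieldProtocol(stages), store="ion")
    apt = cfg_ff.ion_apts().tensors[0]
    fields, means, sems = [], [], []
    for k, stage in enumerate(stages):
        sub = traj_ff.slice_frames(stage_frames(traj_ff, k))
        series = current_density_series(sub, apt)
        m, s = mean_with_blocked_sem(series)
        fields.append(stage.field.magnitude)
        means.append(m)
        sems.append(s)
    fit = conductivity_fit(fields, means, sems)
    lam_ff = molar_conductivity(fit.sigma, conc)
    lam_ff_se = molar_conductivity(fit.sigma_se, conc)

    combined_se = float(np.hypot(lam_ff_se, gk["lambda_se"]))
    return {
        "concentration_mol_per_L": conc,
        "lambda_finite_field": lam_ff,
        "lambda_finite_field_se": lam_ff_se,
        "lambda_green_kubo": gk["lambda_S_cm2_mol"],
        "lambda_green_kubo_se": gk["lambda_se"],
        "D_A2_per_fs": gk["D_A2_per_fs"],
        "combined_se": combined_se,
        "discrepancy": abs(lam_ff - gk["lambda_S_cm2_mol"]),
        "discrepancy_in_se": abs(lam_ff - gk["lambda_S_cm2_mol"]) / combined_se,
        "sigma_S_per_m": fit.sigma,
        "r_squared": fit.r_squared,
        "fields": list(fields),
        "mean_J": list(means),
        "sem_J": list(sems),
        "stage_temperatures_K": traj_ff.metadata["stage_temperatures"],
    }


def regime_experiment(
    preset: str,
    seed: int = 2,
    duration_fs: float = 100_000.0,
    discard_fs: float = 10_000.0,
    sample_every: int = 5,
    fallback_rattle_fs: float | None = None,
    vdos_blocks: tuple = (24, 48, 96),
) -> dict:
    """Zero-field shell regime characterization of one ion preset.

    RDF -> first-minimum cutoff -> shell series -> continuous lifetime,
    VDOS -> rattling period (``fallback_rattle_fs`` is used when the
    spectrum shows no caged-ion band, as for labile shells), and the
    vehicular/structural decomposition of the zero-field current density.
    """
    cfg = preset_config(preset, seed=seed, sample_every=sample_every)
    traj = simulate(cfg, FieldProtocol.zero_field(duration_fs, discard_fs), store="all")
    sub = traj.slice_frames(traj.times >= traj.times[0] + discard_fs)

    rdf = compute_rdf(sub)
    try:
        r0 = detect_first_minimum(rdf)
    except ValueError:
        r0 = 1.45 * cfg.sigma_is  # flat-minimum fallback cutoff
    shell = shell_series(sub, r0)
    tau_c = continuous_lifetime(survival_correlation(shell))

    vd = vdos(sub, 0, block_counts=vdos_blocks)
    try:
        tau_rattle = rattling_period(vd)
    except ValueError:
        tau_rattle = None
    tau_used = tau_rattle if tau_rattle is not None else fallback_rattle_fs
    breakdown = None
    if tau_used is not None:
        series = current_density_series(sub, cfg.ion_apts().tensors[0])
        labels = classify_segments(shell, tau_used)
        breakdown = decompose_current(series, labels)
    return {
        "preset": preset,
        "r0": float(r0),
        "mean_cn": float(shell.cn.mean()),
        "tau_c_fs": float(tau_c),
        "tau_rattle_fs": tau_rattle,
        "tau_rattle_used_fs": tau_used,
        "breakdown": breakdown,
        "vehicular_weight": None if breakdown is None else breakdown.vehicular_weight(),
        "mean_temperature_K": float(traj.metadata["stage_temperatures"][0]),
        "trajectory": sub,
        "shell": shell,
    }


def lifetime_ordering_experiment(
    seed: int = 3,
    duration_fs: float = 60_000.0,
    discard_fs: float = 6_000.0,
    sample_every: int = 5,
    multipliers: dict | None = None,
) -> dict:
    """Continuous lifetimes across the three well-depth multiplier levels.

    The multipliers of the li/na/cs presets are applied to a common
    configuration (same mass and contact distance), isolating the binding
    strength as the stability dial: tau_c rises strictly with the
    multiplier.  The full presets also differ in mass, and Langevin drag
    makes diffusion scale as 1/m, which inflates the heavy labile preset's
    diffusion-limited residence enough to blur the na/cs gap -- see the
    methods note.
    """
    from .simulate import PRESETS, SimConfig

    if multipliers is None:
        multipliers = {k: PRESETS[k][2] for k in ("li", "na", "cs")}
    out = {}
    for name, mult in multipliers.items():
        cfg = SimConfig(ion_well_multiplier=mult, seed=seed, sample_every=sample_every)
        traj = simulate(cfg, FieldProtocol.zero_field(duration_fs, discard_fs), store="all")
        sub = traj.slice_frames(traj.times >= traj.times[0] + discard_fs)
        rdf = compute_rdf(sub)
        try:
            r0 = detect_first_minimum(rdf)
        except ValueError:
            r0 = 1.45 * cfg.sigma_is
        shell = shell_series(sub, r0)
        out[name] = continuous_lifetime(survival_correlation(shell))
    return out
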