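#!/usr/bin/env python
"""Simulate the three shell-stability presets at zero field.

Runs the toy electrolyte (one cation + 200 dipolar solvent particles,
Langevin dynamics at 300 K) for each ion preset -- strongly bound
"li"-like, intermediate "na"-like, labile "cs"-like -- and writes the
sampled trajectories under scratch/ (they are bulky) plus a thermostat
summary under results/.

The downstream structure and lifetime drivers (02, 03) read these files.
"""

import argparse
import json
from pathlib import Path

import ionflow
from ionflow.simulate import FieldProtocol, preset_config

DURATION_FS = 80_000.0
DISCARD_FS = 8_000.0


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--trajdir", type=Path, default=Path("scratch/trajectories"))
    args = ap.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    traj_dir = args.trajdir
    traj_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for preset in ("li", "na", "cs"):
        cfg = preset_config(preset, seed=args.seed, sample_every=5)
        traj = ionflow.simulate(
            cfg, FieldProtocol.zero_field(DURATION_FS, DISCARD_FS), store="all"
        )
        path = traj_dir / f"{preset}_zero_field.extxyz"
        ionflow.write_trajectory(traj, path)
        summary[preset] = {
            "frames": traj.n_frames,
            "mean_temperature_K": traj.metadata["stage_temperatures"][0],
            "trajectory": str(path),
        }
        print(
            f"{preset}: {traj.n_frames} frames, "
            f"<T> = {summary[preset]['mean_temperature_K']:.1f} K -> {path}"
        )
    (args.outdir / "simulation_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
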