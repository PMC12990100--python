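"""Trajectory container, extended-XYZ I/O, APT tables, periodic geometry.

Extended-XYZ dialect
--------------------
Per frame::

    <n_atoms>
    Lattice="L 0 0 0 L 0 0 0 L" Properties=species:S:1:pos:R:3[:vel:R:3][:dipole:R:3] Time=<fs> [Field="ex ey ez"] [Stage=<int>]
    <species> x y z [vx vy vz] [dx dy dz]
    ...

Cells are cubic; coordinates are stored *unwrapped* so displacements and
velocities stay consistent (geometry helpers apply minimum-image wrapping
on demand).  All numerics are written with 10 significant digits.

APT tables are plain text: a header line ``# q_tot=<value>`` followed by
one row per atom: ``index species P_xx P_xy P_xz P_yx ... P_zz``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .field_coupling import AtomicPolarTensorSet, apply_sum_rule_correction

__all__ = [
    "Frame",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "minimum_image_distance",
    "minimum_image_displacement",
    "read_apts",
    "write_apts",
    "AptLoadReport",
]

_FMT = "%.10g"


@dataclass
class Frame:
    """A single snapshot (view into a Trajectory or standalone)."""

    time: float
    box_length: float
    species: Sequence[str]
    positions: np.ndarray  # (N, 3) A
    velocities: np.ndarray | None = None  # (N, 3) A/fs
    dipoles: np.ndarray | None = None  # (N, 3) unit vectors (NaN where absent)
    field: np.ndarray | None = None  # (3,) V/A
    stage: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.positions.shape[0]
        if len(self.species) != n:
            raise ValueError("species/positions length mismatch")
        if self.box_length <= 0:
            raise ValueError("box length must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (n, 3):
                raise ValueError("velocity array shape mismatch")
        if self.dipoles is not None:
            self.dipoles = np.asarray(self.dipoles, dtype=float)
            norms = np.linalg.norm(self.dipoles, axis=1)
            ok = np.isnan(norms) | (np.abs(norms - 1.0) < 1e-8) | (norms == 0.0)
            if not np.all(ok):
                raise ValueError("dipole orientation vectors must be unit-norm")


class Trajectory:
    """Time-ordered frames with a constant atom roster and uniform timestep.

    Arrays are stored frame-major: ``positions[f, i]`` is atom ``i`` in
    frame ``f``.  ``has_velocities`` gates every dynamics analysis.
    """

    def __init__(
        self,
        times: np.ndarray,
        box_length: float,
        species: Sequence[str],
        positions: np.ndarray,
        velocities: np.ndarray | None = None,
        dipoles: np.ndarray | None = None,
        fields: np.ndarray | None = None,
        stage_ids: np.ndarray | None = None,
        metadata: dict | None = None,
    ):
        self.times = np.asarray(times, dtype=float)
        self.box_length = float(box_length)
        self.species = list(species)
        self.positions = np.asarray(positions, dtype=float)
        self.velocities = None if velocities is None else np.asarray(velocities, dtype=float)
        self.dipoles = None if dipoles is None else np.asarray(dipoles, dtype=float)
        self.fields = None if fields is None else np.asarray(fields, dtype=float)
        self.stage_ids = None if stage_ids is None else np.asarray(stage_ids, dtype=int)
        self.metadata = dict(metadata or {})
        self._validate()

    def _validate(self) -> None:
        nf, na = self.positions.shape[:2]
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, atoms, 3)")
        if len(self.species) != na:
            raise ValueError("species list does not match atom count")
        if self.times.shape != (nf,):
            raise ValueError("times do not match frame count")
        if nf > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must be uniform")
        for name in ("velocities", "dipoles"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (nf, na, 3):
                raise ValueError(f"{name} shape mismatch")
        if self.fields is not None and self.fields.shape != (nf, 3):
            raise ValueError("fields must have shape (frames, 3)")

    # -- basic interface -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def timestep(self) -> float:
        if self.n_frames < 2:
            return float(self.metadata.get("timestep", 0.0))
        return float(self.times[1] - self.times[0])

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    def require_velocities(self) -> np.ndarray:
        if self.velocities is None:
            raise ValueError(
                "this analysis requires velocities but the trajectory has none"
            )
        return self.velocities

    def frame(self, i: int) -> Frame:
        return Frame(
            time=float(self.times[i]),
            box_length=self.box_length,
            species=self.species,
            positions=self.positions[i],
            velocities=None if self.velocities is None else self.velocities[i],
            dipoles=None if self.dipoles is None else self.dipoles[i],
            field=None if self.fields is None else self.fields[i],
            stage=None if self.stage_ids is None else int(self.stage_ids[i]),
        )

    def __len__(self) -> int:
        return self.n_frames

    def atom_indices(self, species: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s == species], dtype=int)

    def slice_frames(self, sel) -> "Trajectory":
        return Trajectory(
            times=self.times[sel],
            box_length=self.box_length,
            species=self.species,
            positions=self.positions[sel],
            velocities=None if self.velocities is None else self.velocities[sel],
            dipoles=None if self.dipoles is None else self.dipoles[sel],
            fields=None if self.fields is None else self.fields[sel],
            stage_ids=None if self.stage_ids is None else self.stage_ids[sel],
            metadata=self.metadata,
        )


# -- periodic geometry ---------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Shortest displacement vector(s) b - a under cubic periodic images."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: float) -> float | np.ndarray:
    """Shortest distance between points under cubic periodic boundaries."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


# -- extended-XYZ --------------------------------------------------------

def _parse_comment(line: str, lineno: int) -> dict:
    out: dict = {}
    i = 0
    s = line.strip()
    while i < len(s):
        if s[i].isspace():
            i += 1
            continue
        eq = s.find("=", i)
        if eq < 0:
            raise ValueError(f"line {lineno}: malformed frame header near {s[i:]!r}")
        key = s[i:eq]
        if eq + 1 < len(s) and s[eq + 1] == '"':
            end = s.find('"', eq + 2)
            if end < 0:
                raise ValueError(f"line {lineno}: unterminated quote in frame header")
            out[key] = s[eq + 2 : end]
            i = end + 1
        else:
            end = eq + 1
            while end < len(s) and not s[end].isspace():
                end += 1
            out[key] = s[eq + 1 : end]
            i = end
    return out


def read_trajectory(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory (cubic cell, optional velocities/dipoles)."""
    path = Path(path)
    times, frames_pos, frames_vel, frames_dip, fields, stages = [], [], [], [], [], []
    species: list[str] | None = None
    box_length: float | None = None
    has_vel = has_dip = has_field = has_stage = False

    with path.open() as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                if header == "":
                    break
                continue
            try:
                n_atoms = int(header.split()[0])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: expected atom count, got {header!r}") from exc
            comment = fh.readline()
            lineno += 1
            meta = _parse_comment(comment, lineno)
            lat = meta.get("Lattice")
            if lat is None:
                raise ValueError(f"line {lineno}: frame header lacks Lattice")
            lvals = [float(x) for x in lat.split()]
            L = lvals[0]
            if not np.allclose(lvals, [L, 0, 0, 0, L, 0, 0, 0, L]):
                raise ValueError(f"line {lineno}: only cubic cells are supported")
            props = meta.get("Properties", "species:S:1:pos:R:3")
            cols = props.split(":")
            layout = [(cols[i], int(cols[i + 2])) for i in range(0, len(cols), 3)]
            frame_has_vel = any(name == "vel" for name, _ in layout)
            frame_has_dip = any(name == "dipole" for name, _ in layout)

            spec, pos, vel, dip = [], [], [], []
            for _ in range(n_atoms):
                row = fh.readline()
                lineno += 1
                parts = row.split()
                if not parts:
                    raise ValueError(f"line {lineno}: truncated frame body")
                j = 0
                for name, width in layout:
                    vals = parts[j : j + width]
                    if len(vals) != width:
                        raise ValueError(f"line {lineno}: short atom row for {name}")
                    if name == "species":
                        spec.append(vals[0])
                    elif name == "pos":
                        pos.append([float(v) for v in vals])
                    elif name == "vel":
                        vel.append([float(v) for v in vals])
                    elif name == "dipole":
                        dip.append([float(v) for v in vals])
                    j += width

            if species is None:
                species = spec
                box_length = L
                has_vel, has_dip = frame_has_vel, frame_has_dip
                has_field = "Field" in meta
                has_stage = "Stage" in meta
            else:
                if spec != species or len(spec) != len(species):
                    raise ValueError(f"line {lineno}: inconsistent atom roster across frames")

            times.append(float(meta.get("Time", len(times))))
            frames_pos.append(pos)
            if has_vel:
                frames_vel.append(vel)
            if has_dip:
                frames_dip.append(dip)
            if has_field:
                fields.append([float(x) for x in meta["Field"].split()])
            if has_stage:
                stages.append(int(meta["Stage"]))

    if species is None:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(
        times=np.array(times),
        box_length=float(box_length),
        species=species,
        positions=np.array(frames_pos),
        velocities=np.array(frames_vel) if has_vel else None,
        dipoles=np.array(frames_dip) if has_dip else None,
        fields=np.array(fields) if has_field else None,
        stage_ids=np.array(stages) if has_stage else None,
        metadata={"source": str(path)},
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory in the extended-XYZ dialect described above."""
    path = Path(path)
    L = traj.box_length
    props = "species:S:1:pos:R:3"
    if traj.velocities is not None:
        props += ":vel:R:3"
    if traj.dipoles is not None:
        props += ":dipole:R:3"
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            lat = " ".join(_FMT % v for v in (L, 0, 0, 0, L, 0, 0, 0, L))
            header = f'Lattice="{lat}" Properties={props} Time={_FMT % traj.times[f]}'
            if traj.fields is not None:
                header += ' Field="' + " ".join(_FMT % v for v in traj.fields[f]) + '"'
            if traj.stage_ids is not None:
                header += f" Stage={int(traj.stage_ids[f])}"
            fh.write(header + "\n")
            for i in range(traj.n_atoms):
                row = [traj.species[i]]
                row += [_FMT % v for v in traj.positions[f, i]]
                if traj.velocities is not None:
                    row += [_FMT % v for v in traj.velocities[f, i]]
                if traj.dipoles is not None:
                    row += [_FMT % v for v in traj.dipoles[f, i]]
                fh.write(" ".join(row) + "\n")


# -- APT tables ----------------------------------------------------------

@dataclass
class AptLoadReport:
    """Pre-correction sum-rule deviation recorded at load time."""

    deviation: np.ndarray  # 3x3, sum_i P_i - q_tot I before correction
    max_abs_deviation: float
    corrected: bool


def read_apts(path: str | Path, correct: bool = True) -> tuple[AtomicPolarTensorSet, AptLoadReport]:
    """Load an APT table; by policy the sum-rule correction is applied here.

    Returns the (corrected) tensor set and a load report carrying the
    pre-correction deviation.
    """
    path = Path(path)
    q_tot = 0.0
    species, rows = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                if "q_tot" in s:
                    q_tot = float(s.split("=")[1])
                continue
            parts = s.split()
            if len(parts) != 11:
                raise ValueError(
                    f"{path}:{lineno}: APT rows need index, species and 9 "
                    f"components, got {len(parts)} fields"
                )
            species.append(parts[1])
            rows.append([float(x) for x in parts[2:]])
    tensors = np.array(rows).reshape(-1, 3, 3)
    raw = AtomicPolarTensorSet(tensors=tensors, q_tot=q_tot, species=species)
    deviation = raw.sum_rule_deviation()
    report = AptLoadReport(
        deviation=deviation,
        max_abs_deviation=float(np.max(np.abs(deviation))),
        corrected=correct,
    )
    return (apply_sum_rule_correction(raw) if correct else raw), report


def write_apts(apts: AtomicPolarTensorSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# q_tot={_FMT % apts.q_tot}\n")
        fh.write("# index species P_xx P_xy P_xz P_yx P_yy P_yz P_zx P_zy P_zz\n")
        for i in range(apts.n_atoms):
            sp = apts.species[i] if apts.species is not None else "X"
            comps = " ".join(_FMT % v for v in apts.tensors[i].ravel())
            fh.write(f"{i} {sp} {comps}\n")
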