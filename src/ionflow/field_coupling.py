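"""Field-coupled atomic forces from atomic polar tensors (APTs).

A homogeneous electric field ``eps`` couples to the system through the
dipole operator; to first order the induced force on atom ``i`` along the
Cartesian direction ``eta`` is the contraction of that atom's polar tensor
with the field,

    F^p_{i,eta} = sum_zeta P_{i,eta,zeta} * eps_zeta,

so the total force splits into an unperturbed (zero-field potential) part
and this perturbed part.  The APT of atom ``i`` is the derivative of the
total dipole moment with respect to its position, equivalently the
derivative of its force with respect to the field; its trace/3 is the Born
effective charge.  Exact theory obeys the acoustic sum rule

    sum_i P_{i,eta,zeta} = q_tot * delta_{eta,zeta},

and tabulated/predicted tensors that violate it are repaired by evenly
redistributing the deviation across all atoms, which conserves the total
charge the field acts on.

Units: tensors in e, fields in V/A, forces in e V/A (== eV/A).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AtomicPolarTensorSet",
    "FieldVector",
    "ForceSet",
    "perturbed_forces",
    "apply_sum_rule_correction",
    "born_charge",
    "total_forces",
    "finite_difference_apt",
    "FD_FIELD_INCREMENT",
]

#: default field increment (V/A) for finite-difference APT validation
FD_FIELD_INCREMENT = 0.0257

#: guard against unphysically large fields (V/A)
MAX_FIELD_MAGNITUDE = 0.3

SUM_RULE_TOL = 1e-12


@dataclass(frozen=True)
class FieldVector:
    """A homogeneous electric field in V/A."""

    components: tuple[float, float, float]
    max_magnitude: float = MAX_FIELD_MAGNITUDE

    def __post_init__(self) -> None:
        arr = np.asarray(self.components, dtype=float)
        if arr.shape != (3,):
            raise ValueError("field must have three Cartesian components")
        if not np.all(np.isfinite(arr)):
            raise ValueError("field components must be finite")
        mag = float(np.linalg.norm(arr))
        if mag > self.max_magnitude:
            raise ValueError(
                f"field magnitude {mag:.4g} V/A exceeds the configured "
                f"maximum {self.max_magnitude:.4g} V/A"
            )
        object.__setattr__(self, "components", tuple(float(x) for x in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.components, dtype=float)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.array))

    @classmethod
    def along_z(cls, magnitude: float, max_magnitude: float = MAX_FIELD_MAGNITUDE) -> "FieldVector":
        return cls((0.0, 0.0, float(magnitude)), max_magnitude)


@dataclass
class AtomicPolarTensorSet:
    """Per-atom 3x3 polar tensors (units of e) plus the total charge."""

    tensors: np.ndarray  # (N, 3, 3)
    q_tot: float = 0.0
    species: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must have shape (N, 3, 3)")
        if not np.all(np.isfinite(self.tensors)):
            raise ValueError("polar tensors must be finite")

    def __len__(self) -> int:
        return self.tensors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.tensors.shape[0]

    def born_charges(self) -> np.ndarray:
        """Born effective charge of every atom, q_i = tr(P_i)/3."""
        return np.trace(self.tensors, axis1=1, axis2=2) / 3.0

    def sum_rule_deviation(self) -> np.ndarray:
        """3x3 deviation matrix sum_i P_i - q_tot * I."""
        return self.tensors.sum(axis=0) - self.q_tot * np.eye(3)

    def satisfies_sum_rule(self, tol: float = SUM_RULE_TOL) -> bool:
        return bool(np.max(np.abs(self.sum_rule_deviation())) < tol)


@dataclass
class ForceSet:
    """Per-atom force vectors in e V/A with a provenance tag."""

    forces: np.ndarray  # (N, 3)
    tag: str = "unperturbed"  # unperturbed | perturbed | total

    _TAGS = ("unperturbed", "perturbed", "total")

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise ValueError("forces must have shape (N, 3)")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("force components must be finite")
        if self.tag not in self._TAGS:
            raise ValueError(f"unknown force tag {self.tag!r}")

    @property
    def n_atoms(self) -> int:
        return self.forces.shape[0]


def perturbed_forces(apts: AtomicPolarTensorSet, field_vec: FieldVector,
                     n_atoms: int | None = None) -> ForceSet:
    """Field-induced forces F^p_{i,eta} = sum_zeta P_{i,eta,zeta} eps_zeta."""
    if n_atoms is not None and n_atoms != apts.n_atoms:
        raise ValueError(
            f"APT set covers {apts.n_atoms} atoms but the system has {n_atoms}"
        )
    f = np.einsum("ihz,z->ih", apts.tensors, field_vec.array)
    return ForceSet(f, tag="perturbed")


def apply_sum_rule_correction(apts: AtomicPolarTensorSet) -> AtomicPolarTensorSet:
    """Enforce the acoustic sum rule by even redistribution of the error.

    The deviation ``E = sum_i P_i - q_tot I`` is subtracted in equal shares
    ``E/N`` from every atom, after which ``sum_i P_i = q_tot I`` holds to
    round-off.  Returns a new set; the input is untouched.
    """
    n = apts.n_atoms
    if n == 0:
        raise ValueError("cannot apply the sum rule correction to an empty system")
    deviation = apts.sum_rule_deviation()
    corrected = apts.tensors - deviation[None, :, :] / n
    return replace(apts, tensors=corrected)


def born_charge(apt: np.ndarray) -> float:
    """Born effective charge q = tr(P)/3 of a single 3x3 polar tensor."""
    apt = np.asarray(apt, dtype=float)
    if apt.shape != (3, 3):
        raise ValueError("a single atomic polar tensor must be 3x3")
    return float(np.trace(apt)) / 3.0


def total_forces(base: ForceSet, perturbed: ForceSet) -> ForceSet:
    """Element-wise total force, Eq. F = F^0 + F^p, tagged ``total``."""
    if base.n_atoms != perturbed.n_atoms:
        raise ValueError("force sets cover different numbers of atoms")
    if base.tag != "unperturbed" or perturbed.tag != "perturbed":
        raise ValueError(
            "total_forces combines one 'unperturbed' and one 'perturbed' set, "
            f"got tags {base.tag!r} + {perturbed.tag!r}"
        )
    return ForceSet(base.forces + perturbed.forces, tag="total")


def finite_difference_apt(
    force_model: Callable[[FieldVector], ForceSet],
    increment: float = FD_FIELD_INCREMENT,
    q_tot: float = 0.0,
) -> AtomicPolarTensorSet:
    """Estimate APTs as the central field-derivative of a force model.

    ``P_{i,eta,zeta} ~= (F_{i,eta}(+h e_zeta) - F_{i,eta}(-h e_zeta)) / 2h``
    with ``h = increment`` (V/A).  Exact (to round-off) for a force model
    linear in the field; second-order accurate otherwise.
    """
    if increment <= 0:
        raise ValueError("finite-difference increment must be positive")
    columns = []
    for zeta in range(3):
        e = np.zeros(3)
        e[zeta] = increment
        f_plus = force_model(FieldVector(tuple(e))).forces
        f_minus = force_model(FieldVector(tuple(-e))).forces
        if not (np.all(np.isfinite(f_plus)) and np.all(np.isfinite(f_minus))):
            raise ValueError("force model returned non-finite forces")
        columns.append((f_plus - f_minus) / (2.0 * increment))
    # columns[zeta] has shape (N, 3) = F_{i,eta}; stack into (N, eta, zeta)
    tensors = np.stack(columns, axis=2)
    return AtomicPolarTensorSet(tensors=tensors, q_tot=q_tot)
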