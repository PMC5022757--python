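"""Imaging-frame → applied-field-frame rotation and conductivity tensors.

When the electroporation electrodes define axes that are rotated with
respect to the MRI axes, the region anisotropy vector must be expressed in
the field frame.  The transformation is a composition of counterclockwise
rotations about the imaging axes,

    O = Rz(φ) · Ry(θ) · Rx(α)

with elementary matrices

    Rx(α) = [[1, 0, 0], [0, cosα, sinα], [0, −sinα, cosα]]
    Ry(θ) = [[cosθ, 0, −sinθ], [0, 1, 0], [sinθ, 0, cosθ]]
    Rz(φ) = [[cosφ, −sinφ, 0], [sinφ, cosφ, 0], [0, 0, 1]]

The anisotropy matrix distributes each axis component of A over the rotated
axes as magnitudes, M_ij = A_i·|O_ij|, so row i keeps Euclidean norm A_i;
multiplying by a baseline scalar conductivity σ (S/m) yields the
conductivity tensor handed to field solvers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .regions import AnisotropyVector

log = logging.getLogger(__name__)

#: Convention tag recorded in exports.
ROTATION_CONVENTION = "O=Rz(phi)@Ry(theta)@Rx(alpha), degrees CCW, M_ij=A_i*|O_ij|"

_ORTHO_TOL = 1e-8


class RotationError(ValueError):
    """Raised for invalid axes, angles or frames."""


def _wrap_deg(angle: float) -> float:
    """Normalize an angle in degrees to (−180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class EulerAngles:
    """Counterclockwise rotations (degrees) about x (α), y (θ) and z (φ)."""

    alpha: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("alpha", "theta", "phi"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise RotationError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, _wrap_deg(v))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.theta, self.phi)


def axis_rotation(axis: str, angle_deg: float) -> np.ndarray:
    """Elementary CCW rotation matrix about one imaging axis (degrees)."""
    if not math.isfinite(angle_deg):
        raise RotationError(f"angle must be finite, got {angle_deg}")
    c = math.cos(math.radians(angle_deg))
    s = math.sin(math.radians(angle_deg))
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    if axis == "y":
        return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise RotationError(f"unknown axis {axis!r}; expected 'x', 'y' or 'z'")


def compose_rotation(angles: EulerAngles) -> np.ndarray:
    """Composite transformation O = Rz(φ)·Ry(θ)·Rx(α); orthogonal, det +1."""
    return (
        axis_rotation("z", angles.phi)
        @ axis_rotation("y", angles.theta)
        @ axis_rotation("x", angles.alpha)
    )


def euler_from_axes(field_axes: np.ndarray) -> EulerAngles:
    """Recover Euler angles from a right-handed orthonormal electrode frame.

    ``field_axes`` holds the three field-frame axes as columns.  Returns the
    principal-branch angles whose composition reproduces the input.  At the
    gimbal singularity |θ| = 90° the α = 0 representative is returned and a
    warning is logged.
    """
    O = np.asarray(field_axes, dtype=float)
    if O.shape != (3, 3):
        raise RotationError(f"expected a 3x3 frame, got shape {O.shape}")
    if np.max(np.abs(O.T @ O - np.eye(3))) > _ORTHO_TOL:
        raise RotationError("field axes are not orthonormal")
    if np.linalg.det(O) < 0:
        raise RotationError("field axes form a left-handed frame (det < 0)")
    # O[2,0]=sinθ; O[2,1]=−sinα·cosθ; O[2,2]=cosα·cosθ; O[1,0]=sinφ·cosθ; O[0,0]=cosφ·cosθ
    s_theta = np.clip(O[2, 0], -1.0, 1.0)
    c_theta = math.hypot(O[0, 0], O[1, 0])
    theta = math.degrees(math.atan2(s_theta, c_theta))
    if c_theta < 1e-10:
        log.warning("gimbal singularity |theta|=90 deg; returning the alpha=0 representative")
        alpha = 0.0
        phi = math.degrees(math.atan2(-O[0, 1], O[1, 1]))
    else:
        alpha = math.degrees(math.atan2(-O[2, 1], O[2, 2]))
        phi = math.degrees(math.atan2(O[1, 0], O[0, 0]))
    return EulerAngles(alpha, theta, phi)


def transform_vector(O: np.ndarray, a: AnisotropyVector | np.ndarray) -> np.ndarray:
    """Signed coordinates of an anisotropy vector in the rotated frame, O·A."""
    v = a.as_array() if isinstance(a, AnisotropyVector) else np.asarray(a, dtype=float)
    return np.asarray(O, dtype=float) @ v


@dataclass(frozen=True)
class AnisotropyMatrix:
    """Rotated 3×3 anisotropy magnitude matrix with its provenance."""

    matrix: np.ndarray
    source: AnisotropyVector
    angles: EulerAngles
    symmetric: bool = False
    convention: str = ROTATION_CONVENTION


@dataclass(frozen=True)
class ConductivityTensor:
    """Entrywise σ-scaled anisotropy matrix, in S/m."""

    matrix: np.ndarray
    sigma: float
    source: AnisotropyMatrix
    tissue: str | int | None = None


def anisotropy_matrix(
    a: AnisotropyVector,
    angles: EulerAngles,
    symmetric: bool = False,
) -> AnisotropyMatrix:
    """Distribute the region anisotropy components over the field-frame axes.

    Default construction: M_ij = A_i·|O_ij| (row i has norm A_i; zero angles
    give diag(A)).  With ``symmetric=True`` the physically symmetric tensor
    rotation O·diag(A)·Oᵀ is used instead, for solvers that require a
    symmetric conductivity tensor.
    """
    O = compose_rotation(angles)
    if symmetric:
        m = O @ np.diag(a.as_array()) @ O.T
    else:
        m = a.as_array()[:, None] * np.abs(O)
    return AnisotropyMatrix(m, a, angles, symmetric=symmetric)


def conductivity_tensor(
    m: AnisotropyMatrix,
    sigma: float,
    tissue: str | int | None = None,
) -> ConductivityTensor:
    """Scale an anisotropy matrix by the tissue's baseline conductivity (S/m)."""
    if not (sigma > 0):
        raise RotationError(f"baseline conductivity must be positive, got {sigma}")
    return ConductivityTensor(sigma * m.matrix, float(sigma), m, tissue=tissue)
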