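"""Per-voxel diffusion-tensor estimation and scalar/axis map derivation.

The single-tensor model relates the diffusion-weighted signal to a symmetric
3×3 tensor D (mm²/s):

    S(b, g) = S0 · exp(−b · gᵀ D g)

``fit_tensor`` solves the log-linearized model by least squares,
``tensor_eigensystem`` decomposes the field into sorted eigenvalues and
orthonormal eigenvectors, and ``scalar_maps`` / ``dec_axis_map`` derive the
mean diffusivity (ADC), fractional anisotropy (FA) and the
directionally-encoded axis map FA·|e1| used for per-axis anisotropy
aggregation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gradients import GradientScheme, GradientSchemeError

log = logging.getLogger(__name__)

#: Component order of the 6-vector tensor storage.
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

#: Axis-semantics tag recorded with every volume: x = left→right,
#: y = anterior→posterior (front→back), z = head→foot.
AXIS_SEMANTICS = "x:L-R y:A-P z:H-F"


class TensorModelError(ValueError):
    """Raised for ill-posed fits or invalid tensor fields."""


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal (x, y, z, acquisition) with its scheme."""

    signal: np.ndarray
    voxel_size: tuple[float, float, float]
    scheme: GradientScheme
    axis_semantics: str = AXIS_SEMANTICS

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be a 4-D array (x, y, z, acquisition)")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension ({self.signal.shape[3]}) must equal the scheme "
                f"length ({len(self.scheme)})"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class LabelMask:
    """Integer region labels on the DWI grid: 1=tumor, 2=soft tissue, 3=bone, 0=background."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    codes: dict[int, str] = field(default_factory=lambda: {1: "tumor", 2: "soft_tissue", 3: "bone"})

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.int16)
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.codes)
        if unknown:
            raise ValueError(f"mask contains labels outside the declared code set: {sorted(unknown)}")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor as 6 unique components (mm²/s).

    ``components[..., :]`` follows :data:`TENSOR_COMPONENTS`.  ``valid`` marks
    voxels where a tensor was actually estimated (or defined, for phantoms).
    """

    components: np.ndarray
    voxel_size: tuple[float, float, float]
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape[-1] != 6:
            raise ValueError("tensor field must have 6 components on the last axis")
        if self.valid is None:
            self.valid = np.ones(self.components.shape[:-1], dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.components.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric (..., 3, 3) matrices."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.components, -1, 0)
        m = np.empty(self.components.shape[:-1] + (3, 3))
        m[..., 0, 0] = dxx
        m[..., 1, 1] = dyy
        m[..., 2, 2] = dzz
        m[..., 0, 1] = m[..., 1, 0] = dxy
        m[..., 0, 2] = m[..., 2, 0] = dxz
        m[..., 1, 2] = m[..., 2, 1] = dyz
        return m

    @classmethod
    def from_matrices(
        cls,
        matrices: np.ndarray,
        voxel_size: tuple[float, float, float],
        valid: Optional[np.ndarray] = None,
    ) -> "TensorField":
        m = np.asarray(matrices, dtype=float)
        comps = np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
            axis=-1,
        )
        return cls(comps, voxel_size, valid)


@dataclass
class EigenSystem:
    """Sorted per-voxel eigen-decomposition: λ1 ≥ λ2 ≥ λ3 with orthonormal e1..e3."""

    eigenvalues: np.ndarray   # (..., 3) descending
    eigenvectors: np.ndarray  # (..., 3, 3); [..., :, i] is the i-th eigenvector
    voxel_size: tuple[float, float, float]
    n_clamped: int = 0

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.eigenvalues.shape[:-1]

    @property
    def e1(self) -> np.ndarray:
        """Principal eigenvector field, (..., 3)."""
        return self.eigenvectors[..., :, 0]


@dataclass
class ScalarMap:
    """Per-voxel scalar map with a kind tag ('FA' dimensionless or 'ADC' mm²/s)."""

    data: np.ndarray
    kind: str
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kind == "FA" and (np.any(self.data < 0) or np.any(self.data > 1 + 1e-12)):
            raise ValueError("FA values must lie in [0, 1]")
        if self.kind == "ADC" and np.any(self.data < 0):
            raise ValueError("ADC values must be non-negative")


@dataclass
class AxisMap:
    """Directionally-encoded per-voxel vector (FA·|e1,x|, FA·|e1,y|, FA·|e1,z|)."""

    data: np.ndarray  # (..., 3), componentwise >= 0
    voxel_size: tuple[float, float, float]
    axis_semantics: str = AXIS_SEMANTICS

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, −b·gx², −b·gy², −b·gz², −2b·gxgy, −2b·gxgz, −2b·gygz].

    Solving X·[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] = ln S linearizes the
    single-tensor signal equation.
    """
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx * gx,
            -bvals * gy * gy,
            -bvals * gz * gz,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
        ]
    )


def fit_tensor(
    dwi: DWIVolume,
    mask: Optional[LabelMask] = None,
    weighted: bool = False,
) -> TensorField:
    """Fit the diffusion tensor voxelwise by log-linear least squares.

    Multiple b=0 volumes are averaged into a single baseline before the log
    transform.  Voxels containing non-positive signal among the fitted
    acquisitions are flagged invalid, excluded and counted in the log.

    Parameters
    ----------
    dwi : DWIVolume
    mask : LabelMask, optional
        If given, only voxels with label > 0 are fitted; the rest stay empty.
    weighted : bool
        Use the signal-squared weighted variant (one reweighting pass from the
        ordinary solution) instead of ordinary least squares.
    """
    scheme = dwi.scheme
    scheme.validate_for_fit()
    b0 = scheme.b0_mask
    if len(scheme) - scheme.n_b0 + 1 < 7:
        raise TensorModelError("fewer than 7 usable acquisitions after b=0 averaging")

    if mask is not None and mask.labels.shape != dwi.grid_shape:
        raise TensorModelError(
            f"mask shape {mask.labels.shape} does not match DWI grid {dwi.grid_shape}"
        )
    in_fit = np.ones(dwi.grid_shape, dtype=bool) if mask is None else mask.labels > 0

    # collapse the b=0 volumes to their mean, then build one shared design
    s_b0 = dwi.signal[..., b0].mean(axis=-1, keepdims=True)
    s_dw = dwi.signal[..., ~b0]
    signals = np.concatenate([s_b0, s_dw], axis=-1)
    bvals = np.concatenate([[0.0], scheme.bvals[~b0]])
    bvecs = np.vstack([np.zeros(3), scheme.bvecs[~b0]])
    X = _design_matrix(bvals, bvecs)

    usable = in_fit & np.all(signals > 0, axis=-1)
    n_excluded = int(np.count_nonzero(in_fit & ~usable))
    if n_excluded:
        log.warning("excluded %d voxels with non-positive signal from the tensor fit", n_excluded)

    comps = np.zeros(dwi.grid_shape + (6,))
    if np.any(usable):
        y = np.log(signals[usable])  # (nvox, nacq)
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, nvox)
        if weighted:
            # one generalized-least-squares pass with weights = predicted S²
            w = np.exp(X @ beta) ** 2  # (nacq, nvox)
            xtwx = np.einsum("ki,kn,kj->nij", X, w, X)
            xtwy = np.einsum("ki,kn,nk->ni", X, w, y)
            beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0].T
        comps[usable] = beta[1:].T
    return TensorField(comps, dwi.voxel_size, valid=usable)


def tensor_eigensystem(field: TensorField) -> EigenSystem:
    """Sorted orthonormal eigen-decomposition of a tensor field.

    Negative eigenvalues (noise artifacts) are clamped to zero and counted.
    Eigenvector signs are fixed by making each vector's largest-magnitude
    component positive; only absolute components are consumed downstream.
    """
    if not np.all(np.isfinite(field.components)):
        bad = np.argwhere(~np.all(np.isfinite(field.components), axis=-1))[0]
        raise TensorModelError(
            f"non-finite tensor entries at voxel {tuple(int(i) for i in bad)}"
        )
    mats = field.as_matrices()
    vals, vecs = np.linalg.eigh(mats)            # ascending
    vals = vals[..., ::-1]                       # descending
    vecs = vecs[..., :, ::-1]
    n_clamped = int(np.count_nonzero((vals < 0) & field.valid[..., None]))
    if n_clamped:
        log.warning("clamped %d negative eigenvalues to zero", n_clamped)
    vals = np.clip(vals, 0.0, None)
    # sign convention: largest-|component| positive
    idx = np.argmax(np.abs(vecs), axis=-2, keepdims=True)
    sign = np.sign(np.take_along_axis(vecs, idx, axis=-2))
    sign[sign == 0] = 1.0
    vecs = vecs * sign
    return EigenSystem(vals, vecs, field.voxel_size, n_clamped=n_clamped)


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖, with FA = 0 where all eigenvalues vanish."""
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam * lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def scalar_maps(eig: EigenSystem) -> tuple[ScalarMap, ScalarMap]:
    """FA and ADC maps from a sorted eigensystem (ADC = mean eigenvalue)."""
    fa = fractional_anisotropy(eig.eigenvalues)
    adc = eig.eigenvalues.mean(axis=-1)
    return (
        ScalarMap(fa, "FA", eig.voxel_size),
        ScalarMap(adc, "ADC", eig.voxel_size),
    )


def dec_axis_map(eig: EigenSystem, fa: ScalarMap) -> AxisMap:
    """Directionally-encoded axis map FA·|e1| (red/green/blue = L-R / A-P / H-F).

    Invariant under the sign of e1; the Euclidean norm at each voxel equals FA.
    """
    if eig.grid_shape != fa.data.shape:
        raise TensorModelError(
            f"eigensystem grid {eig.grid_shape} does not match FA grid {fa.data.shape}"
        )
    return AxisMap(fa.data[..., None] * np.abs(eig.e1), eig.voxel_size)
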