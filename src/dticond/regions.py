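"""Per-region anisotropy vectors and the isotropy-error statistic.

For a labelled region the per-voxel directionally-encoded vectors FA·|e1|
are summed and unit-normalized, giving the region anisotropy vector
A = (Ax, Ay, Az) on the imaging axes (x = left→right, y = front→back,
z = head→foot).  If conductivity were isotropic each component would equal
1/√3 ≈ 0.577; the isotropy error quantifies, per axis, the relative
deviation from that reference:

    err_i = 100 · |A_i − 1/√3| / (1/√3)   [%]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor import AxisMap, LabelMask

#: Per-axis component of a directionless unit vector, 1/√3 ≈ 0.577.
ISOTROPIC_REFERENCE = 1.0 / math.sqrt(3.0)

#: Validator tolerance on ‖A‖ = 1 for externally supplied vectors; vectors
#: reported to 3 decimals stay within ~0.011 of unit norm.
NORM_TOLERANCE = 0.011


class RegionError(ValueError):
    """Raised for empty or degenerate regions and invalid vectors."""


@dataclass(frozen=True)
class AnisotropyVector:
    """Unit vector of per-axis anisotropy for one region.

    Componentwise non-negative with Euclidean norm 1 (within
    :data:`NORM_TOLERANCE` for vectors supplied at reduced precision).
    """

    label: int | str
    components: tuple[float, float, float]
    n_voxels: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.components, dtype=float)
        if a.shape != (3,):
            raise RegionError("anisotropy vector needs exactly 3 components")
        if np.any(a < 0):
            raise RegionError(f"components must be non-negative, got {tuple(a)}")
        norm = float(np.linalg.norm(a))
        if abs(norm - 1.0) > NORM_TOLERANCE:
            raise RegionError(f"components must have unit norm (got {norm:.4f})")
        object.__setattr__(self, "components", tuple(float(v) for v in a))

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.components))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.components, dtype=float)


@dataclass(frozen=True)
class IsotropyErrorReport:
    """Per-axis relative deviation from the 1/√3 isotropic reference, in %."""

    raw_pct: tuple[float, float, float]
    integer_pct: tuple[int, int, int]
    reference: float = ISOTROPIC_REFERENCE
    rounding: str = "truncate"


def region_axis_vector(axis_map: AxisMap, mask: LabelMask, label: int) -> AnisotropyVector:
    """Aggregate a region's FA·|e1| field into its unit anisotropy vector.

    The per-voxel axis vectors are summed (an FA-weighted mean of principal
    directions up to normalization) and the sum is unit-normalized.
    """
    if mask.labels.shape != axis_map.grid_shape:
        raise RegionError(
            f"mask shape {mask.labels.shape} does not match axis map grid {axis_map.grid_shape}"
        )
    sel = mask.labels == label
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise RegionError(f"region label {label} has no voxels in the mask")
    v = axis_map.data[sel].sum(axis=0)
    norm = float(np.linalg.norm(v))
    if norm <= 0:
        raise RegionError(f"region label {label} is degenerate: all axis vectors are zero")
    return AnisotropyVector(label, tuple(v / norm), n_voxels=n)


def isotropy_error(a: AnisotropyVector, rounding: str = "truncate") -> IsotropyErrorReport:
    """Per-axis error (%) committed by assuming isotropic conductivity.

    ``rounding`` selects how the integer column is derived from the raw
    percentages: ``"truncate"`` (toward zero, the default) or ``"nearest"``.
    Raw values are always retained.
    """
    raw = tuple(
        100.0 * abs(c - ISOTROPIC_REFERENCE) / ISOTROPIC_REFERENCE for c in a.components
    )
    if rounding == "truncate":
        ints = tuple(int(r) for r in raw)
    elif rounding == "nearest":
        ints = tuple(int(round(r)) for r in raw)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return IsotropyErrorReport(raw, ints, rounding=rounding)


@dataclass
class RegionSummary:
    """One row per (case, tissue): anisotropy vector plus isotropy errors."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        case: str,
        tissue: str,
        vector: AnisotropyVector,
        report: IsotropyErrorReport,
    ) -> None:
        ax, ay, az = vector.components
        ex, ey, ez = report.integer_pct
        self.rows.append(
            {
                "case": case,
                "tissue": tissue,
                "Ax": ax,
                "Ay": ay,
                "Az": az,
                "err_x": ex,
                "err_y": ey,
                "err_z": ez,
                "n_voxels": vector.n_voxels,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["case", "tissue", "Ax", "Ay", "Az", "err_x", "err_y", "err_z", "n_voxels"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fa_component_range(summary: RegionSummary, tissue: str) -> tuple[float, float]:
    """Min and max per-axis anisotropy components over all cases of a tissue."""
    df = summary.to_frame()
    sub = df[df["tissue"] == tissue]
    if sub.empty:
        raise RegionError(f"no summary rows for tissue {tissue!r}")
    comps = sub[["Ax", "Ay", "Az"]].to_numpy(dtype=float)
    return float(comps.min()), float(comps.max())
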