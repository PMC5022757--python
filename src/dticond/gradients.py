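"""Diffusion gradient schemes and the bval/bvec text dialect.

A :class:`GradientScheme` describes one acquisition per entry: a b-factor in
s/mm² and a unit gradient direction.  b = 0 entries carry the conventional
(0, 0, 0) direction.  The default multi-shell scheme uses b = 800 and
1000 s/mm² with 30 directions per shell spread by electrostatic repulsion,
plus one unweighted baseline per shell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: b-values (s/mm²) of the default multi-shell acquisition.
DEFAULT_SHELLS = (800.0, 1000.0)
#: Default number of gradient directions per shell.
DEFAULT_N_DIRECTIONS = 30


class GradientSchemeError(ValueError):
    """Raised when a gradient table violates the scheme invariants."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-acquisition b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion weighting per acquisition volume, s/mm², non-negative.
    bvecs : (n, 3) array
        Unit direction per volume; (0, 0, 0) for b = 0 entries.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.shape != (bvals.size, 3):
            raise GradientSchemeError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise GradientSchemeError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise GradientSchemeError("diffusion-weighted directions must be unit vectors")
        if np.any(norms[~dw] > 1e-12):
            raise GradientSchemeError("b=0 entries must carry the (0,0,0) direction")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    def validate_for_fit(self) -> None:
        """Check the scheme can support a six-component tensor fit."""
        if self.n_b0 < 1:
            raise GradientSchemeError("tensor fitting requires at least one b=0 volume")
        dirs = self.bvecs[~self.b0_mask]
        # directions equal up to sign probe the same tensor projection
        uniq: list[np.ndarray] = []
        for g in dirs:
            if not any(min(np.linalg.norm(g - u), np.linalg.norm(g + u)) < 1e-8 for u in uniq):
                uniq.append(g)
        if len(uniq) < 6:
            raise GradientSchemeError(
                f"tensor fitting requires >= 6 distinct directions, got {len(uniq)}"
            )


def repulsion_directions(n: int, n_iter: int = 200, step: float = 5e-3) -> np.ndarray:
    """Spread ``n`` unit vectors on the half-sphere by electrostatic repulsion.

    Starts from a deterministic Fibonacci spiral and relaxes pairwise
    antipodally-symmetric Coulomb forces projected onto the sphere.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (i + 0.5) / n  # upper hemisphere only; sign is irrelevant for DWI
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([r * np.cos(ga * i), r * np.sin(ga * i), z])
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):  # each direction repels both poles of the others
            diff = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            force += np.sum(diff / (dist2[..., None] ** 1.5 + 1e-12), axis=1)
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def default_scheme(
    n_directions: int = DEFAULT_N_DIRECTIONS,
    shells: tuple[float, ...] = DEFAULT_SHELLS,
) -> GradientScheme:
    """Multi-shell scheme: one b=0 per shell plus ``n_directions`` per shell."""
    dirs = repulsion_directions(n_directions)
    bvals: list[float] = []
    bvecs: list[np.ndarray] = []
    for b in shells:
        bvals.append(0.0)
        bvecs.append(np.zeros(3))
        bvals.extend([float(b)] * n_directions)
        bvecs.extend(dirs)
    return GradientScheme(np.array(bvals), np.array(bvecs))


def write_bval_bvec(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write the two-file text dialect: one row of b-values, three rows of components."""
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    rows = [" ".join(f"{c:.10g}" for c in scheme.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read a bval/bvec pair, re-normalizing slightly off-unit directions."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3:
        raise GradientSchemeError(
            f"bvec table must have exactly 3 rows of components, got {bvecs.shape[0]}"
        )
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise GradientSchemeError(
            f"bvec columns ({bvecs.shape[0]}) do not match bval entries ({bvals.size})"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    off = dw & (np.abs(norms - 1.0) > 1e-3)
    if np.any(off):
        log.warning("re-normalizing %d gradient directions off unit length by > 1e-3",
                    int(np.count_nonzero(off)))
    safe = norms.copy()
    safe[~dw] = 1.0
    safe[safe == 0] = 1.0
    bvecs = np.where(dw[:, None], bvecs / safe[:, None], 0.0)
    return GradientScheme(bvals, bvecs)
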