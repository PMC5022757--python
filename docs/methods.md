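# Methods

## Signal model and tensor estimation

The package assumes Gaussian (single-compartment) diffusion per voxel:
`S(b, g) = S0·exp(−b·gᵀDg)` with D a symmetric positive-semidefinite 3×3
tensor in mm²/s. The estimator is ordinary log-linear least squares on
`ln S = ln S0 − b·gᵀDg`, solving for seven parameters (ln S0 and the six
unique tensor components) with one shared design matrix per acquisition
scheme. All b=0 volumes are averaged into a single baseline row before the
log transform, which stabilizes the intercept without biasing the slope
terms. A weighted variant (`weighted=True`) performs one
generalized-least-squares pass with weights equal to the predicted squared
signal — the usual first-order correction for the log transform's
heteroscedasticity; it is off by default because the noise-free contracts
and the reference workflow assume the plain estimator.

Voxels containing a non-positive signal among the fitted acquisitions
cannot enter the log transform; they are excluded, zero-filled, flagged in
`TensorField.valid` and counted in the run log. After eigen-decomposition
(LAPACK symmetric solver, eigenvalues re-sorted descending) any negative
eigenvalues are clamped to zero and counted; FA is computed after clamping,
which keeps it in [0, 1] by construction. Eigenvector signs are fixed by
making each vector's largest-magnitude component positive; this is purely
cosmetic since every downstream consumer uses absolute components.

## Region aggregation

The per-voxel directionally-encoded vector is FA·|e1| on the imaging axes
(x = left→right, y = front→back, z = head→foot). A region's anisotropy
vector is the unit-normalized sum of these vectors. Normalization is
adopted because measured per-region vectors of this kind sit on the unit
sphere to within rounding (the bundled cohort's nine vectors have norms in
[0.9995, 1.0099]), making ‖A‖ = 1 a structural constraint rather than a
convention choice. The aggregation is FA-weighted: voxels with stronger
anisotropy contribute proportionally more direction information, and the
result is invariant to a global rescaling of FA within the region. An
unweighted mean of |e1| differs negligibly after normalization for the
region sizes involved.

The isotropy error per axis is `100·|A_i − 1/√3|/(1/√3)` %. Integer
reporting truncates toward zero by default — the mode that reproduces the
cohort's unambiguous reported cells — with a `nearest` switch; raw
percentages are always retained. Some of the cohort's reported integer
cells are internally scrambled (axis permutations within a row); the
bundled fixture flags, per cell, whether the reported integer matches the
formula, and only consistent cells participate in numeric checks.

## Frame rotation and conductivity

The applied-field frame is reached by counterclockwise rotations about the
imaging axes composed as `O = Rz(φ)·Ry(θ)·Rx(α)` with

    Rx(α) = [[1, 0, 0], [0, c, s], [0, −s, c]]
    Ry(θ) = [[c, 0, −s], [0, 1, 0], [s, 0, c]]
    Rz(φ) = [[c, −s, 0], [s, c, 0], [0, 0, 1]]

This sign/order convention is pinned by a reproduction test: applied to the
bundled cohort's vectors and angles it regenerates all 54 published rotated
matrix entries of the leg and thigh cases to within ±0.002 at 3-decimal
precision. (The forearm case's published block is internally inconsistent
with its own angles under every sign/order variant we tried and is excluded
from numeric checks.) Angle extraction (`euler_from_axes`) inverts the
composition via θ = asin(O31), α = atan2(−O32, O33), φ = atan2(O21, O11),
returning the α = 0 representative with a logged warning at the |θ| = 90°
gimbal singularity.

The anisotropy matrix is `M_ij = A_i·|O_ij|`: each imaging-axis component
is distributed over the field axes as magnitudes, so row i keeps norm A_i
and zero angles give diag(A). M is generally non-symmetric; because some
finite-element solvers require a symmetric conductivity tensor, the
physically standard congruence `O·diag(A)·Oᵀ` is available behind
`symmetric=True` (default off, matching the reference construction).
Conductivity tensors are the entrywise product σ·M with a per-tissue
baseline σ in S/m supplied by the user — no baselines ship with the
package since they are protocol- and frequency-dependent.

## Synthetic phantom

`make_limb_phantom` emulates an axial limb cross-section on an 80×80×20
grid at 3×3×4 mm (240 mm in-plane field of view, 4 mm slices): a muscle
cylinder (label 2), an off-center bone core (label 3) and a tumor ellipsoid
(label 1), with validation that the regions are disjoint and inside the
limb. Each tissue has ground-truth eigenvalues and a principal-direction
field: per voxel, the direction is the normalized sum of the tissue's mean
axis and an isotropic Gaussian perturbation with standard deviation
`dispersion` (seeded, reproducible). Defaults: muscle (1.7, 0.2, 0.2)
×10⁻³ mm²/s along z with dispersion 1.1; tumor (1.4, 0.55, 0.45)×10⁻³
along an oblique axis with dispersion 1.3; bone (0.6, 0.25, 0.25)×10⁻³
along z with dispersion 1.0. The dispersions were chosen so the default
phantom's region anisotropy vectors have all components inside the
0.475–0.70 band observed in the reference cohort — i.e. regions that are
partially, not perfectly, oriented. Setting dispersion to 0 gives coherent
single-orientation regions used by the recovery contracts.

`simulate_dwi` evaluates the exponential decay exactly and, when
`noise_sigma > 0`, applies Rician noise as the magnitude of two independent
Gaussian channels from a seeded generator. Background (air) voxels emit
zero true signal and therefore carry Rayleigh noise, as in real magnitude
MRI. The default gradient scheme is two shells (b = 800, 1000 s/mm²) of 30
directions spread by electrostatic repulsion from a deterministic Fibonacci
start, plus one b=0 per shell; the direction count of the reference
acquisition is not documented, so no claim of matching it is made.

What the phantom does **not** emulate: eddy-current and motion artifacts,
susceptibility distortion, partial-volume mixing at tissue borders,
multi-compartment diffusion, spatially varying S0, or coil-profile noise
correlation. Passing recovery tests therefore demonstrates correctness of
the estimator and the aggregation chain under the stated signal model, not
robustness to real-scanner artifacts.

## Numerical choices and problem sizes

- Tolerances: eigenvector orthonormality asserted to 1e−10; noise-free
  tensor round trip to 1e−8 relative, with exactly-zero components judged
  relative to the voxel's dominant component; produced region vectors unit
  to 1e−9; rotation orthogonality to 1e−10; Euler round trip to 1e−8.
- Degenerate inputs: all-zero eigenvalues give FA = 0 by convention; empty
  or all-zero regions raise errors naming the label; non-finite tensor
  entries raise an error naming the voxel.
- Test problem sizes: unit and property tests run on 24×24×8 phantoms at
  10 mm isotropic spacing (same 240×240×80 mm physical extent as the
  default grid) with 12-direction shells; the oracle-equivalence check uses
  a 10×10×10 grid; the acceptance script uses 24×24×8 with the full
  30-direction scheme. The full 80×80×20 default fits and aggregates in a
  couple of seconds.

## Known limitations

- The non-symmetric `M = diag(A)·|O|` construction is a bookkeeping of
  anisotropy magnitudes per field axis, not a tensor transformation; use
  the symmetric flag when a solver interprets the matrix as a rank-2
  tensor.
- FA is a surrogate for conductivity anisotropy; the proportionality of
  the two is an assumption of the approach, not something this package can
  validate.
- Masks must already be aligned to the DWI grid; no registration or
  resampling is performed.
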