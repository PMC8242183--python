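# Methods

This note records the models implemented in `srrmri`, the conventions and
numerical choices behind them, and what the synthetic experiments do and do
not demonstrate.

## Acquisition forward model

A thick-slice 2D multi-slice scan is modeled on the reconstruction lattice
as `y_k = D_k H_k T_k x + e_k`.

- **Pose `T_k`.** A rigid transform (extrinsic x-y-z rotation angles in
  radians, translation in mm, rotation about a stated world center)
  applied by resampling with third-order B-spline interpolation
  (`scipy.ndimage.map_coordinates` with spline prefiltering, so the
  interpolant passes exactly through the samples). Grids are always
  axis-aligned; all obliquity lives in `T_k`. Out-of-field samples are
  filled with 0, the background level of magnitude MRI; this boundary
  policy is a package decision, as is the canonical RAS-like reorientation
  applied on NIfTI load.
- **Slice profile `H_k`.** A Gaussian low-pass along the slice axis with
  FWHM equal to the slice thickness, i.e. sigma = thickness / (2 sqrt(2 ln 2))
  (0.849 mm for 2 mm slices). No in-plane PSF is modeled: 2D Fourier
  encoding leaves the in-plane resolution unchanged. Slice cross-talk and
  the interleaved excitation order are not modeled; the interleave order is
  exposed in the protocol module as scanner metadata only.
- **Downsampling `D_k`.** Implemented in the frequency domain: the
  DC-centered unitary FFT along the slice axis is multiplied by the
  Gaussian transfer `exp(-2 pi^2 sigma^2 f^2)` and truncated to the
  `n_slices` lowest frequencies. For even retained lengths the band keeps
  the negative-Nyquist sample and drops the positive one — an arbitrary but
  fixed convention enforced by the adjoint tests. After truncation the data
  are scaled by `sqrt(n_lr / n_hr)`, the factor that makes a constant image
  keep its value under the unitary convention, so tissue intensities agree
  between HR and LR images. Slices are contiguous:
  `n_slices = round(extent / thickness)`.
- **Adjoint.** The transpose operator zero-fills the missing high
  frequencies, applies the (real, symmetric) transfer, and inverts the
  pose by resampling with the inverse transform. Two variants are exposed:
  the plain l2 adjoint (used in the solver gradient, exact for identity
  poses — verified to 1e-6 by inner-product tests) and a voxel-volume
  weighted adjoint (the adjoint under physically weighted inner products)
  which preserves constants in both directions. The adjoint of an
  interpolated rigid warp is approximated by the inverse warp; this is
  standard practice and the solver's backtracking absorbs the small
  mismatch.
- **Noise.** Additive i.i.d. Gaussian (valid for magnitude MRI at
  SNR > 3), seeded per scan as `seed + scan_index` for independent,
  reproducible streams.

## Gradient guidance and the solver

The inverse problem is

`min_x sum_k ||A_k x - y_k||^2 + lambda sum_s ||grad_s x - g_s||_1`

with the literal objective (no 1/2 factor; lambda not rescaled by the
number of scans or components). `grad_s` is the circular shift-difference
`I - D_x^a D_y^b D_z^c` with integer shifts a in [-2, 2] and b, c in
[0, 2], excluding the all-zero triple and triples with negative coordinate
sum (which duplicate orientations up to sign); 40 components remain.
The guidance `g_s` is the same operator applied to the IAA image — the
voxelwise mean of the scans after B-spline upsampling to the HR grid and
alignment — computed once and frozen: the L1 term then pulls the
reconstruction's local gradients toward the IAA's edge structure without
re-smoothing homogeneous regions. Components are unweighted and raw (no
normalization by shift length): the multi-scale set itself provides the
scale mixing.

Minimization is subgradient descent with a backtracking line search on the
total objective: a step is accepted only if it does not increase the
objective, so the trace is non-increasing by construction; if 40 halvings
find no decrease the iteration stops (at an L1 kink the subgradient need
not be a descent direction — with `sign(0) = 0` any exact fit is a fixed
point). The initial step is `1/L` with `L` estimated by seeded power
iteration on the data-term Hessian `2 sum_k A_k^T A_k`. Defaults:
`lambda = 0.1`, `max_iters = 100`, `tol = 1e-5` on the relative objective
change, initialization at the IAA image (which guarantees the final
objective is no worse than IAA's). A fixed-step mode exists for analysis
and raises, with the trace attached, after five consecutive objective
increases. The TV baseline runs the identical machinery with the guidance
replaced by zero fields over the six unit shift-differences (anisotropic
TV with circular boundary), weight fixed at 0.1; single-image SRR is the
same solver with n = 1.

## Registration

When poses are unknown, each HR-interpolated scan is aligned to the first
by maximizing mutual information over the six rigid parameters. The MI
estimator uses a 32-bin joint histogram over mutually in-field voxels,
intensities clipped to each image's 1st-99th percentiles, reported in
nats. Optimization is Powell's method (derivative-free, deterministic)
with a two-level coarse-to-fine schedule (half resolution after Gaussian
smoothing, then full resolution), linear interpolation inside the loop for
speed, and the rotation center at the fixed volume's world center. If the
final MI is below the initialization's, the initialization is returned
with a warning. The estimator internals are implementation-defined; they
are validated by recovery of known simulated motion (2 mm / 2 degrees
recovered to well under 0.5 mm / 0.5 degrees on noiseless phantoms) and by
inverse-consistency.

## Quality assessment

- **Partial-volume estimation.** A 3-component Gaussian mixture is fit by
  EM to the intensities of an analysis region containing all three
  tissues (scikit-learn backend; components initialized at the
  25th/50th/75th percentiles with equal weights; spherical covariances;
  convergence tolerance 1e-6 on the mean per-sample log-likelihood;
  deterministic under the seed). A voxel is *pure* if it lies within
  mu +/- delta of some component, with delta = sigma sqrt(2 ln 2) (half
  the component FWHM); the PVE is the percentage of region voxels that
  are not pure. Note the estimator's analytic floor: even perfectly pure
  Gaussian classes leave `1 - erf(sqrt(ln 2)) ~ 23.9%` of their own draws
  outside the FWHM interval, so PVE values are comparative, not absolute.
  The default analysis region is the Otsu foreground eroded by one voxel;
  the default background region is the eight corner cubes of 10% linear
  size. Both are overridable by masks.
- **SNR / CNR.** `SNR = 10 log10(sum w_k s_k / (sigma sum w_k))` with
  component means `s_k`, weights `w_k` and background-noise sd `sigma`
  (sample sd over the background region). The default weighting takes
  `w_k` as the peak height of the weighted component density,
  `pi_k / (sigma_k sqrt(2 pi))`; mixing proportions are exposed as an
  alternative (`weight_mode='mixing'`) since both readings are defensible
  and they coincide for equal component sds.
  `CNR = 10 log10(|s_i - s_j| / sigma)` per tissue pair; a pair with
  identical means has undefined (NaN) CNR. Component-to-tissue assignment
  follows the contrast: ascending means are (GM, WM, CSF) for T2-like and
  (CSF, GM, WM) for T1-like images.
- **PSNR / SSIM.** PSNR uses the reference maximum as peak. SSIM is the
  standard structural-similarity index with an 11-voxel Gaussian window
  (sigma 1.5) and default stabilizers, averaged over the volume
  (scikit-image backend).

## Protocol arithmetic

`scan_time` evaluates `T = TR ceil(FoV_p / (S_p f_acc ETL)) N_NEX`.
`max_tr` inverts it for TR under a time budget; by default the shot count
is treated as continuous because the protocol's published worked value
(13.1 s for a 120 s budget at FoV 150 mm, 0.39 mm, R = 2, ETL 21) only
arises without the ceiling — the integer-shot answer (12.0 s) is available
via `apply_ceiling=True`, and the discrepancy is documented rather than
hidden. The slice order helper returns the even-first ascending
interleave-2 permutation for any N (for odd N the naive "evens then odds
to N-1" recipe would drop the last slice; the permutation property is kept
instead). `hr_tradeoff` reproduces the standard arithmetic chain for
matching a thick-slice protocol by direct HR acquisition — data factor
`(v_lr/v_hr)^3`, time scaled by the squared ratio, and averages equal to
the squared (one-decimal-rounded) data factor, with the exact value also
returned.

## Synthetic phantom

The phantom emulates the geometry relevant to the reconstruction problem:
nested smooth shapes (outer CSF shell, convoluted GM ribbon, WM core,
background air at 0) built from an ellipsoidal radial field perturbed by
smoothed seeded noise and a few random bumps, voxelized at 0.5 mm on a
96^3 default grid (64^3 in the scripted experiment, a desk-scale choice).
Intensities are class means plus optional i.i.d. Gaussian noise
(default sd 10 against T2-like means CSF/GM/WM = 300/100/200, i.e. tissue
SNR of roughly 20-30 dB, comfortably inside the additive-Gaussian regime);
the noiseless background corner regions support noise-sd estimation.
Everything is deterministic under the geometry seed.

The phantom is deliberately not an anatomical atlas: no bias field, no
Rician noise floor, no skull/scalp compartments, no within-class texture,
and tissue interfaces that are smooth-random rather than cortically
folded. Passing end-to-end tests therefore demonstrates the correctness
and the qualitative behavior of the operators, solver and metrics (SRR
recovering resolution that IAA averages away; regularization helping at
moderate weights and collapsing to IAA at large ones), not clinical
performance on real neonatal data.

## Problem sizes and runtime choices

Unit tests run at 4^3-48^3; the end-to-end recovery test runs the full
three-orthogonal-scan study at 96^3 with 15 solver iterations per lambda,
and the acceptance script uses 64^3 with 25 iterations plus small random
inter-scan motion (±0.7 mm, ±0.5 degrees) and per-scan noise sd 10. These
sizes keep a complete run in minutes on one CPU while leaving every
operator on the same code path as a full-size problem; reconstruction
cost scales linearly with voxel count.

## Known limitations

- The rigid-warp adjoint is approximate (inverse-warp resampling), so
  descent steps near convergence can stall slightly earlier with large
  motion than with identity poses.
- Subgradient descent handles the L1 term without smoothing or proximal
  splitting; convergence near kinks is conservative (backtracking stops
  rather than oscillates). A proximal variant would converge faster but
  shares the same fixed points.
- The PVE estimator inherits the FWHM-interval floor discussed above and
  is sensitive to the analysis-region choice; region masks should be held
  fixed across methods being compared.
- k-space raw data, coil sensitivities, parallel-imaging reconstruction
  and T1/T2 signal equations are out of scope: contrast is inherited from
  the input volume.
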