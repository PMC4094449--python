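# Methods

This note records the models, discretizations and design choices behind
`mreitaw`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and grid conventions

All 2-D fields are sampled at pixel centers of a uniform grid; arrays
are indexed `[row, col]`, physical *x* grows with the column index and
*y* with the row index, and the origin sits at the center of the field
of view.  All geometry is in meters, conductivity in S/m, flux density
in tesla.  One gradient stencil — central differences inside the support
mask, one-sided on its boundary — is shared by the forward model, the
reconstruction and the evaluation metric, so that discrete identities
(e.g. annihilation of constants by the rotated gradient) hold across
module boundaries.

## Phantom

The default phantom emulates a saline tank experiment: a disc of
0.4 S/m (radius 0.4·FOV) containing D1 (1.5 S/m disc), D2 (0.1 S/m
disc) and D3 (1.5 S/m core wrapped in a 0.3 S/m annulus).  Pixels take
the innermost region containing their center; no anti-aliasing, so the
truth is piecewise constant and the ROI variance metric is meaningful.
Inclusion radii (0.20/0.20/0.13-in-0.22 of the disc radius) and
positions (three-fold arrangement at 0.52 disc radii) are package
choices — the emulated experiment specifies materials and
conductivities but not the exact geometry — and are fully configurable.

The magnitude image is region-wise constant: 30 (arbitrary units) in
the background and 4 inside all inclusions, with magnitude noise std 1,
i.e. SNR ≈ 30 against ≈ 4.  This reproduces the regime that motivates
the filter: short-T2 objects whose MR signal — and hence flux-density
quality — collapses while the surrounding saline stays clean.

## Forward model

**Voltage.**  ∇·σ∇u = 0 with Neumann data from two opposite boundary
electrodes (default width 80 mm, current 10 mA) is discretized by a
5-point finite-volume scheme with harmonic face averaging of σ; the
injected current is split equally over the electrode's boundary faces,
so the compatibility condition Σg = 0 holds exactly.  The singular
system is closed by a zero-mean Lagrange constraint, which is also the
voltage gauge.  A slab thickness (default 4 mm) converts the injected
current to an areal current density.  The solver reproduces the 1-D
analytic strip solution to ~1e−15 relative.

**Biot–Savart.**  Bz at the pixel centers is a discrete sum over source
pixels, evaluated fast by FFT cross-correlations (verified against the
direct double sum to 1e−12).  Two kernels are available:

* `tall` (default): each source column is integrated along z, giving
  the 1/ρ² line-current kernel.  This is the correct idealization for
  objects much taller than the imaging slice (the tank and animal
  geometry), and it satisfies the in-plane curl identity
  ∇⊥Bz = μ₀J at **all** wavelengths, which keeps the
  single-differentiation reconstruction quantitatively consistent.
* `slab`: each source pixel is a small volume (pixel area × slab
  thickness) concentrated in the slice.  This kernel attenuates the
  recovered contrast by a wavenumber-dependent factor ≈ t·k/2 and is
  provided for sensitivity studies, not as the default.

The self-pixel term is zero (the integrand is odd over a symmetric
pixel).

**Acquisition and extraction.**  The ± current acquisitions are
simulated in the image domain, S± = M e^{iδ} e^{±iγBzTc} plus i.i.d.
complex Gaussian noise (under ideal full sampling this is equivalent to
adding the noise in k-space).  Bz is extracted as
arg(S⁺·conj(S⁻))/(2γTc); the systematic phase δ cancels exactly.  The
per-channel noise scale is s/√2 where s is the magnitude noise level, so
the magnitude SNR Υ = M/s propagates to exactly sd(Bz) = 1/(2γTcΥ) — the
standard spin-echo phase-noise law — which Monte-Carlo tests confirm to
within 2% at Υ ∈ {10, 50, 100}.  The law is taken valid for Υ > 2.8;
below that the noise-std map is clamped at the threshold value and the
pixels are flagged.  The simulation enforces |γBzTc| < π/2 (no phase
wrapping; unwrapping is out of scope).

**Injection time.**  Tc is experiment-specific.  The default pipeline
uses 2 ms, chosen once from the phase-wrap margin: the default phantom
at 10 mA gives max |γBzTc| ≈ 0.43 rad, a 3.7× safety factor, while
leaving the inclusions clearly noise-dominated (sd(Bz) ≈ 2.3e−7 T at
Υ = 4 against a ~8e−7 T signal range).

## Reconstruction

Single-pass transversal J-substitution from two orthogonal injections:

σ = σ_H − (1/μ₀)·[Σₙ ∇⊥(Bz,ₙ − Bz,ₙᴴ)·∇uₙᴴ] / [Σₙ |∇uₙᴴ|²]

with σ_H the homogeneous reference (the background conductivity in
synthetic mode, a user parameter for real data).  The update is local:
perturbing Bz inside a region changes σ only within one stencil width of
it, which is why a position-adaptive *post*-filter is effective.  The
denominator is floored at 1e−6 of its maximum (guarding electrode
shadows); floored pixels are flagged.

Because the correction is computed against the homogeneous current
pattern and applied once, contrast recovery is partial by construction:
a 2-D disc inclusion of conductivity σ_i in background σ_b reconstructs
to σ_i·2σ_b/(σ_b + σ_i) (the shielded-disc field factor) — about 45% of
a small contrast.  The implementation matches this analytic prediction
to ~2% on a noiseless low-contrast phantom; no fixed-point iteration is
attempted, since the method under study applies the formula once.  The
variance-reduction results are unaffected (they compare the same
reconstruction before and after filtering).

## Adaptive filter

Parameter maps are derived from the noise-std map, expressed on the SNR
scale (sd(Bz) and Υ are bijective at fixed Tc):

* h(r) = max(h_floor, c_h · sd(r)/sd_ref), in magnitude units,
* η(r) = min(η_max, round_half_up(c_eta · sd(r)/sd_ref)), in pixels,
* η(r) = 0 wherever the local SNR exceeds `snr_quiet` (quiet pixels).

Both maps are monotone nondecreasing in the local noise level.
Defaults: sd_ref is the noise level at SNR `snr_ref` = 12, c_h = 1.0,
c_eta = 2.0, η_max = 6, h_floor = 5% of the magnitude dynamic range,
`snr_quiet` = 40.  The normalization is **absolute** (a reference noise
level, not a data quantile): with uniformly good data the filter
degenerates to the identity, which is the "do no harm" property — at
SNR ≥ 50 everywhere the output is bit-identical to the input.  At the
phantom's object SNR of ≈ 4 the maps reach η = 6 and h ≈ 3·(range/30),
i.e. full-size, nearly flat kernels, while the background-to-object
magnitude step of ~26 units suppresses cross-boundary weights by
e^(−26/h) — edges survive aggressive in-region averaging.  The
constants were calibrated on the synthetic phantom; the proportionality
constants are an acknowledged open end of the method itself and remain
exposed (`--c-h`, `--c-eta`, `--eta-max`, `--h-floor`).

The neighborhood is a Euclidean disc clipped to the support, center
included.  The measured (noisy) magnitude is used as-is — the method
specifies no pre-smoothing of M.  The implementation clips each output
pixel to the min/max of its kernel values, so the convex-combination
bound holds exactly in floating point; with a singleton kernel the
output is bit-identical to the input.

The error split σ_w − σ_t = (bias within the kernel) + (averaged noise)
is available for synthetic data as per-pixel maps E1, E2 with
|σ_w − σ_t| ≤ E1 + E2; E1 vanishes wherever a kernel sits inside one
homogeneous region.

## Evaluation

V_D(σ) is the RMS gradient magnitude over the ROI, computed only on
pixels whose full central-difference stencil lies inside the ROI, so
that true region edges do not contaminate the score; adding a constant
to σ leaves it invariant.  Percent reduction is 100·(1 − V_after/V_before)
and the headline number is the mean over the three homogeneous inclusion
ROIs (D1, D2, D3 core).

**Baseline.**  The comparison denoiser is the explicit reaction-
diffusion iteration v ← v + α∇·(∇v/|∇v|) − β(v − f), v⁰ = f, in the
standard dimensionless (pixel-unit) form with the gradient magnitude
floored (default 1e−8); physical-unit curvature at millimeter spacing
would be unconditionally unstable at α = 0.1.  The explicit floored-TV
scheme has a residual variance floor ≈ α/pixel, so the variance-matching
helper anneals β (first) and α (second) whenever the ROI variance
stalls — this implements the protocol of choosing the baseline's
parameters so that its noisy-ROI variance equals the adaptive filter's
before comparing side effects.

**Comparison experiment.**  The baseline comparison is run with
magnitude noise 0.3 (background SNR ≈ 100, inclusions ≈ 13): the
question being tested is what each method does to regions whose data are
*trustworthy*, so the background must actually be quiet, as in the
in-vivo situation the comparison mimics.  Under the headline conditions
(background SNR ≈ 30) the background is itself noisy and a gradient-
variance metric there simply rewards whichever method smooths more,
which measures noise removal, not blur.  With a quiet background the
adaptive filter leaves it bit-exact (V inflation 1.00) while the
variance-matched baseline inflates background V by ~1.3× through edge
motion and staircasing.

## Problem sizes and determinism

The shipped experiments run at the study's native 128×128 matrix; a
full pipeline run takes a few seconds on one CPU (sparse direct solve of
~11.5k unknowns per injection, FFT Biot–Savart, vectorized filtering),
and the acceptance script (five noise realizations) well under a
minute.  Every stochastic operation takes an explicit seed and uses one
documented generator; per-injection seeds are derived via
`SeedSequence`.  Reruns with the same configuration and seed are
bit-identical, including written artifacts.

## What the synthetic tests do not show

* The phantom's piecewise-constant magnitude and conductivity make the
  filter's core assumption — pixels with similar magnitude have similar
  conductivity — exactly true except across the D3 core/annulus
  boundary (two materials, same low magnitude level), where averaging
  mixes real contrast.  In vivo this assumption can fail more broadly;
  quantitative values in noisy regions should be read from both the
  filtered and unfiltered images.
* No k-space trajectory, coil, multi-echo or relaxation simulation; no
  phase unwrapping (|γBzTc| ≥ π/2 is rejected, not handled); no 3-D
  multi-slice coupling.
* Absolute V values depend on grid spacing and noise scale; only
  percent reductions are comparable across setups.
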