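# Methods

This note records the model assumptions, the parameter choices that matter,
what the synthetic generators do and do not emulate, and the numerical
decisions made where the design was genuinely open.

## Imaging model and discretization

Fields live on the input plane S = [-1/2, 1/2]², discretized on a uniform
pixel-center lattice.  All discrete inner products use the midpoint
quadrature rule with weight equal to the pixel area, which approximates the
L² inner product to O(h²) and keeps every Gram computation a single
weighted matrix product.  Coordinates are fixed once for all modules: pixel
centers, 0-based indexing, axis 0 = x₁.  The 2D Fourier system uses the
square index set k₁, k₂ ∈ {-√K/2, …, √K/2 − 1} (K a perfect even square),
enumerated row-major with k₁ outer; its discrete Gram is the identity to
1e-10 whenever the grid has at least 2·max|k| pixels per axis (no
aliasing among the represented frequencies).

The device is a bounded linear operator with a spatially-variant kernel
coupling the two polarizations.  The simulator realizes it as a truncated
singular expansion: random band-limited fields orthonormalized per
polarization as input and output modes, singular value
s_j = exp(−decay_rate · j / n_modes), and a per-mode 2×2 unitary coupling
block interpolated between the identity (coupling_strength = 0) and a
random unitary (coupling_strength = 1) with polar re-unitarization.  This
gives direct, independent control of the two properties that drive the
inverse problem: spectral decay (conditioning) and polarization mixing.
Sensor sampling reads the pixel containing each sensor point (no
interpolation — the measurement model is pointwise) and adds i.i.d.
circular complex Gaussian noise of total standard deviation `noise_sigma`
per entry.  No physical fiber properties (mode solving, bending,
temperature drift, diffraction) are modeled; conclusions about real fibers
rest only on linearity, spectral decay and coupling, which the simulator
shares with them.

## Calibration and system assembly

A scalar calibration function probes one polarization at a time, so each
E_m is sent as two or three vector inputs differing by a unit-modulus
factor on the vertical component (b = e^{iβ}, optionally c = e^{iγ} with
c ≠ b, b + c ≠ 2).  The default scheme is β = π/2, γ = π, which satisfies
both constraints and spreads the three phase factors over the unit circle;
no particular values are required by the algebra, and they are plain
configuration.  The polarization-isolating combinations are exact algebraic
identities for any valid scheme and are verified to machine precision over
random schemes in the tests.  Measurement rows interleave h, v per sensor
point; calibration noise is independent per exposure.  The three-input
variant averages two independent exposures per combination and is the
default because it is less noise-sensitive.

The change-of-basis matrix H solves the Gram-matrix normal equations with
an optional ridge of 1e-10 × the mean Gram diagonal (the Gram conditioning,
not the solver, is the practical limit).  Residual norms per column report
‖H_k − Σ_m h_{m,k} E_m‖ on the grid and certify how well the calibration
span covers the representation system; in the bundled study the spot
lattice must be fine enough (roughly two spots per shortest represented
wavelength) or the high-frequency coefficients — exactly the feature-bearing
ones — are reconstructed poorly.

## Solvers

Naive inversion, least squares and Tikhonov are the printed closed forms.
The ℓ1 solver is FISTA on ½‖g − EHf‖₂² + λ‖f‖₁ with the complex
soft-threshold acting on the modulus (phase preserved), step 0.99/L with L
estimated by 50 power iterations, tol 1e-6 on the relative coefficient
change, max_iter 2000.  Note the data term is squared; the unsquared
variant traverses the same solution path under a reparameterization of λ,
so λ values are not transferable between conventions.  λ may be given
relative to ‖(EH)ᴴg‖∞ (`lam_relative`), which makes it scale-free across
instances; the bundled study uses λ_rel = 0.005 — small, because smooth
phantoms are *not* sparse in the Fourier basis and heavier shrinkage
suppresses the high-frequency tail that carries the scattering feature.
A grid-search-with-holdout helper for λ is provided but is not a default.

On a seeded ill-conditioned instance (decay_rate 8, sensor noise 0.02,
noiseless calibration, 3-sparse truth) the reconstruction errors order as
ℓ1 < ℓ2 < least squares < naive; the instance parameters are part of the
study definition, chosen so each failure mode (noise amplification for LS,
scale mismatch for naive) is actually expressed.

## Tissue phantoms

1D family: F(x) = exp(−x²)·exp(iτ sin 20x) on [−1/2, 1/2].  The default
eight τ values are linearly spaced in [0.5, 2.8]: the instantaneous
frequency of the phase factor reaches ≈ 3.2τ cycles, so τ beyond ≈ 3
pushes spectral mass outside the 20-coefficient window [−10, 10) and the
Gaussian fit degenerates, while below ≈ 0.5 the fitted σ no longer responds
to τ.

2D phantom: (side+100)² uniform noise in [−1, 1] → Gaussian low-pass with
std ρ pixels (kernel truncated at radius ⌈2ρ⌉, replicate padding) → crop 50
pixels per side → affine rescale of [min, max] onto [−τ, τ] (so both
endpoints are attained exactly, making the range testable).  Amplitude:
exp(−50‖x‖²)/1000 plus five blobs exp(−‖x−c‖²/d)/2000 with c uniform in
[−0.4, 0.4]² (keeps blobs inside S) and d log-uniform in [0.005, 0.05]
(blob radii ≈ 0.07–0.22).  Default image side 700; at other sizes ρ is
rescaled proportionally so the correlation length is preserved in physical
units.

The six (τ, ρ) categories default to τ log-spaced in [1.2, π] and 1/ρ
log-spaced in [0.03, 0.08] per pixel (at the 700-pixel reference).  The
upper 1/ρ stops at 0.08 because the phase bandwidth n/(2πρ) then reaches
≈ 9, still inside the ±10 window of the 20×20 coefficient set; at
1/ρ = 0.125 the bandwidth (≈ 14) exceeds the window, the in-window spectrum
flattens, and the fitted feature becomes unstable and non-monotone.  The
category-monotonicity evaluation pairs categories on common seeds — each
seed generates the same amplitude and the same pre-filter phase noise for
all six categories — so the category contrast is not masked by
amplitude-draw variability.

## Features

The decay feature fits an axis-aligned 5-parameter Gaussian (damped
nonlinear least squares, moment-based initialization, positivity via
optimizing log σ) to the Fourier-transform modulus approximated from the
first 20×20 Fourier coefficients on a 0.25-step lattice over [−10, 10)²
(0.1 in 1D); halving the step changes fitted σ by well under 0.1%.  The 2D
feature sinc-interpolates the coefficient *moduli*: the modulus lattice is
exactly invariant to whole-pixel shifts and global phase offsets of the
field, so the feature is too.  (Interpolating the complex transform first
and then taking the modulus breaks shift invariance by a few percent
because off-lattice phases beat; the 1D demo keeps that variant for its
|FT| panels, where no invariance is claimed.)

Phase unwrapping uses reliability-ordered unwrapping
(`skimage.restoration.unwrap_phase`); its contract — output congruent to
the input modulo 2π pixelwise, smooth true phase recovered up to one global
2π offset — is what the pipeline relies on.  Welch's t-test is
`scipy.stats.ttest_ind(equal_var=False)`, cross-checked in the tests
against a from-scratch evaluation of the t statistic, the
Welch–Satterthwaite degrees of freedom and the two-sided p-value.  When the
two polarizations are combined, each polarization's per-area means are
z-scored by their overall mean/std across all areas and the two z-scores
are averaged per area before a single test; the averaging rule is a
documented choice — equal weighting is the neutral default absent any
reason to prefer one polarization.

## Problem sizes

The bundled study runs on a 64×64 grid with a 10×10 spot calibration,
160 fiber modes, 2048 sensor points and K = 100 coefficients per
polarization; `StudyConfig.full_window()` scales to a 25×25 calibration,
800 modes and K = 400 (the full feature window), which tracks ground-truth
phantom features closely at a few minutes' cost.  Category monotonicity is
evaluated at image side 200 and the two-class power study at side 128 with
6 areas × 6 sub-images per class over 100 repetitions; these sizes keep the
phase-bandwidth-to-window geometry of the 700-pixel reference (ρ is
rescaled) while keeping a full run to minutes on one CPU.

## Known limitations

* The simulator's mode fields are smooth and band-limited; real fiber modes
  have structure (core confinement, speckle) the tests do not exercise.
* The phantom generator emulates phase-scattering statistics only; no
  physical scattering, speckle or absorption model stands behind it, so
  passing tests show the *pipeline* responds to phase-oscillation strength,
  not that real lesions produce these statistics.
* The decay feature saturates once phase bandwidth exceeds the 20×20
  coefficient window; fields oscillating faster than the window are
  indistinguishable from one another.
* Time variation of the kernel (bending, temperature) is out of scope; the
  operator is fixed between calibration and imaging.
* The wavelet representation system is a generic separable orthonormal
  periodized construction, not a boundary-corrected one; near-boundary
  coefficients mix across the periodic seam.
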