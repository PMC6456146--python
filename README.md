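# fibrec

Reconstruction of complex optical vector-fields — amplitude, phase and both
polarization states — from measurements taken through an imaging device
whose transmission operator is unknown, such as a multicore-fiber endoscope,
together with a Fourier-decay *scattering feature* that separates strongly
phase-scattering (lesion-like) tissue from weakly scattering (healthy-like)
tissue.

## Who this is for

Researchers in computational imaging and biophotonics who need to

* characterize an unknown linear imaging operator from calibration
  input/output pairs and invert it stably (phase conjugation, least squares,
  Tikhonov, or complex-LASSO ℓ1 regularization),
* recover an image in a representation basis (e.g. Fourier) *different*
  from the calibration basis (e.g. localized spots), directly from raw
  measurements, and
* quantify phase scattering via the decay of the recovered Fourier
  coefficients.

No physical device is required: a seeded synthetic fiber simulator and a
simulated tissue-phantom generator reproduce the full pipeline at desk
scale.

## The model

The device maps the field F at the distal (tissue-side) plane
S = [-1/2, 1/2]² to the sensor-side field F̃ through an unknown
spatially-variant kernel G:

    F̃(y) = ∫_S G(y, x) F(x) dx ,      F : S → ℂ²  (h and v polarizations)

Calibration sends M known scalar functions E_m through the device in
polarization-multiplexed triples

    A_m = [E_m; E_m],   B_m = [E_m; b·E_m],   C_m = [E_m; c·E_m]

with unit-modulus phase factors b = e^{iβ}, c = e^{iγ} (c ≠ b, b + c ≠ 2).
Exact linear combinations of the *measured outputs* isolate each input
polarization, giving the joint linear system

    g = E H f + ε,
    E = [ a*(A − (b*/2)B − (c*/2)C) ,  a(A − B/2 − C/2) ],   a = 1/(1 − b/2 − c/2)

where H is the (block-diagonal) change-of-basis matrix expressing the
desired representation system {H_k} in the calibration system {E_m},
estimated from Gram matrices.  The coefficient vector f (K per
polarization) is recovered by one of

1. naive inversion (phase conjugation)  f̄ = (EH)ᴴ g,
2. least squares  f̄ = ((EH)ᴴ EH)⁻¹ (EH)ᴴ g,
3. Tikhonov / ℓ2  f̄ = ((EH)ᴴ EH + λI)⁻¹ (EH)ᴴ g,
4. complex LASSO / ℓ1  f̄ = argmin ½‖g − EHf‖₂² + λ‖f‖₁  (FISTA with a
   modulus soft-threshold that preserves the phase).

The scattering feature: fit an axis-aligned Gaussian
a·exp(−(w₁−c₁)²/2σ₁² − (w₂−c₂)²/2σ₂²) to the modulus of the Fourier
transform approximated from the first 20×20 Fourier coefficients by
Whittaker–Shannon sinc interpolation; σ₁+σ₂ is the feature.  Slower
coefficient decay (larger σ₁+σ₂) indicates stronger phase scattering.
Per-sample features are averaged per tissue area and the healthy/lesion
classes are compared with Welch's t-test.

## Worked example

Run the bundled synthetic two-class study (64×64 grid, 100-spot
calibration, K = 100 Fourier coefficients per polarization recovered with
ℓ1 regularization, 3 healthy and 3 lesion areas with 3 sub-images each):

```bash
fibrec run-study --out study_demo
```

which prints (abridged):

```
h: t=-3.6557 df=2.42 p=0.05001
v: t=-10.3775 df=2.80 p=0.00255
combined: t=-7.4358 df=2.09 p=0.01566
feature table: 36 rows -> study_demo
```

The healthy areas (phantom category 2: phase amplitude τ ≈ 1.45 rad,
smoothing ρ ≈ 27 px at the 700-px reference) give a mean recovered feature
σ₁+σ₂ ≈ 2.93 while the lesion areas (category 5: τ ≈ 2.59, ρ ≈ 15 px) give
≈ 5.47: stronger phase
oscillation survives the fiber, the calibration and the regularized
inversion, and remains detectable in the recovered Fourier coefficients
(Welch p < 0.05 for the v polarization and for the combined z-scored
feature).  `study_demo/feature_table.tsv` holds the per-sub-image features;
`study_demo/report.json` the test results.

The 1D illustration of why the feature works (oscillating-phase family
exp(−x²)·e^{iτ sin 20x}, its interpolated |FT| and the fitted σ for eight
increasing τ):

```bash
fibrec demo-1d --out demo1d
# sigma increases from 0.514 to 23.186 over tau 0.50..2.80 -> demo1d
```

Individual pipeline stages are exposed as `make-kernel`, `calibrate`,
`phantom`, `reconstruct`, `features` and `analyze`; all artifacts are
zip-of-named-array archives plus JSON metadata and tab-delimited feature
tables.  The same functionality is available as a library:

```python
import fibrec as fr

grid = fr.make_grid(64)
kernel = fr.make_kernel(seed=7, n_modes=160, decay_rate=1.0,
                        coupling_strength=0.7, grid=grid)
spots = fr.spot_basis(fr.spot_lattice(10, grid), 0.04, grid)
fourier = fr.fourier_basis(400, grid)
H = fr.change_of_basis(spots, fourier).H
```

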