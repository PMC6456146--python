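"""Simulated tissue phantoms with controllable phase scattering.

Increased scattering in abnormal tissue shows up as faster spatial
oscillation of the optical phase.  Two generators emulate this:

* a 1D family F(x) = exp(-x^2) * exp(i tau sin(20 x)) on [-1/2, 1/2], where
  tau sets the magnitude of the phase oscillation, and
* a 2D phantom F = R * exp(i P) on a 700x700 discretization of the unit
  square, where the phase P is low-pass-filtered uniform noise rescaled to
  [-tau, tau] (smoothing std rho, in pixels) and the amplitude R is a small
  sum of Gaussian blobs.

Larger tau (amplitude) or smaller rho (correlation length) means stronger
phase oscillation, hence slower decay of the Fourier coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, ScalarField, make_grid

DEFAULT_SIDE = 700
CROP_MARGIN = 50  # pixels removed from each boundary after filtering


@dataclass(frozen=True)
class TissueParams:
    """Phase-oscillation parameters of the 2D phantom.

    tau: phase amplitude in [0, pi] (radians); rho: Gaussian smoothing std
    in pixels; seed: phase-noise seed.
    """

    tau: float
    rho: float
    seed: int
    side: int = DEFAULT_SIDE

    def __post_init__(self) -> None:
        if not 0 <= self.tau <= np.pi:
            raise ValueError("tau must lie in [0, pi]")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.side < 2:
            raise ValueError("side must be >= 2")


def example_field_1d(tau: float, n_points: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """The 1D example field exp(-x^2) exp(i tau sin(20 x)) at pixel centers.

    Returns ``(x, F)`` on a uniform discretization of [-1/2, 1/2].
    """
    if n_points < 64:
        raise ValueError("need at least 64 sample points")
    if not 0 <= tau < 2 * np.pi:
        raise ValueError("tau must lie in [0, 2*pi)")
    x = (np.arange(n_points) + 0.5) / n_points - 0.5
    F = np.exp(-(x**2)) * np.exp(1j * tau * np.sin(20 * x))
    return x, F


def fourier_coeffs_1d(F: np.ndarray, n_coeffs: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature Fourier coefficients f_k = int F(x) e^{-2 pi i k x} dx.

    Indices run k = -n_coeffs/2, ..., n_coeffs/2 - 1 (the first ``n_coeffs``
    coefficients, default -10..9).  Returns ``(k, f_k)``.
    """
    F = np.asarray(F).ravel()
    n = F.size
    if n < 64:
        raise ValueError("too few samples for stable quadrature (need >= 64)")
    half = n_coeffs // 2
    k = np.arange(-half, n_coeffs - half)
    # pixel centers x_j = (j + 1/2)/n - 1/2; the sum is an FFT up to a
    # per-frequency phase from the half-pixel offset and the -1/2 shift
    spec = np.fft.fft(F) / n
    phase = np.exp(2j * np.pi * k * (n - 1) / (2 * n))
    return k, spec[k % n] * phase


def fourier_coeffs_2d(
    values: np.ndarray, n_coeffs: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """First n_coeffs x n_coeffs 2D Fourier coefficients by FFT quadrature.

    ``values`` is the field on a uniform pixel-center grid over the unit
    square.  Returns ``(k, f)`` with ``k`` the (n_coeffs^2, 2) index set,
    row-major with k1 outer, and ``f`` the matching coefficient vector.
    """
    V = np.asarray(values)
    if V.ndim != 2:
        raise ValueError("expected a 2D field")
    n1, n2 = V.shape
    half = n_coeffs // 2
    ks = np.arange(-half, n_coeffs - half)
    spec = np.fft.fft2(V) / (n1 * n2)
    p1 = np.exp(2j * np.pi * ks * (n1 - 1) / (2 * n1))
    p2 = np.exp(2j * np.pi * ks * (n2 - 1) / (2 * n2))
    block = spec[np.ix_(ks % n1, ks % n2)] * np.outer(p1, p2)
    K1, K2 = np.meshgrid(ks, ks, indexing="ij")
    k = np.column_stack([K1.ravel(), K2.ravel()])
    return k, block.ravel()


def tissue_phase_2d(params: TissueParams) -> np.ndarray:
    """Random smooth phase image, rescaled to [-tau, tau].

    Pipeline: (side+100)^2 pixels uniform in [-1, 1] -> Gaussian low-pass
    with std rho (kernel truncated at radius ceil(2 rho), replicate
    padding) -> crop 50 pixels from each boundary -> affine rescale mapping
    [min, max] onto [-tau, tau].  Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    raw_side = params.side + 2 * CROP_MARGIN
    raw = rng.uniform(-1.0, 1.0, size=(raw_side, raw_side))
    radius = int(np.ceil(2 * params.rho))
    filtered = gaussian_filter(
        raw, sigma=params.rho, mode="nearest", truncate=radius / params.rho
    )
    cropped = filtered[CROP_MARGIN:-CROP_MARGIN, CROP_MARGIN:-CROP_MARGIN]
    lo, hi = cropped.min(), cropped.max()
    if params.tau == 0 or hi == lo:
        return np.zeros_like(cropped)
    return (cropped - lo) / (hi - lo) * (2 * params.tau) - params.tau


def tissue_amplitude_2d(seed: int, grid: GridSpec | None = None, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Random amplitude image: a sum of Gaussian blobs on the unit square.

    The fixed central blob exp(-50 |x|^2)/1000 plus five blobs
    exp(-|x - c|^2 / d)/2000 with c uniform in [-0.4, 0.4]^2 and d
    log-uniform in [0.005, 0.05]; strictly positive everywhere.
    """
    if grid is None:
        grid = make_grid((side, side))
    rng = np.random.default_rng(seed)
    x = grid.centers()
    r2 = (x**2).sum(axis=1)
    R = np.exp(-50.0 * r2) / 1000.0
    for _ in range(5):
        c = rng.uniform(-0.4, 0.4, size=2)
        d = np.exp(rng.uniform(np.log(0.005), np.log(0.05)))
        R = R + np.exp(-((x - c) ** 2).sum(axis=1) / d) / 2000.0
    return R.reshape(grid.shape)


def make_tissue_image(params: TissueParams, seed_amp: int) -> ScalarField:
    """Complex phantom F = R exp(i P) on a side x side grid over S."""
    P = tissue_phase_2d(params)
    grid = make_grid((params.side, params.side))
    R = tissue_amplitude_2d(seed_amp, grid)
    F = R * np.exp(1j * P)
    return ScalarField(F.ravel(), grid)


def default_categories(n: int = 6, side: int = DEFAULT_SIDE) -> list[TissueParams]:
    """Six (tau, rho) categories with increasing phase oscillation.

    tau increases log-spaced up to pi and 1/rho increases log-spaced up to
    0.08/pixel; rho is stated in pixels of the default 700-pixel image and
    is rescaled proportionally for other sizes so the correlation length is
    preserved in physical units.  The upper 1/rho keeps the phase bandwidth
    inside the +-10 window spanned by the 20x20 coefficient set, so the
    fitted decay feature remains a faithful summary in every category.
    """
    taus = np.geomspace(1.2, np.pi, n)
    inv_rhos = np.geomspace(0.03, 0.08, n)
    scale = side / DEFAULT_SIDE
    return [
        TissueParams(tau=float(t), rho=float(scale / ir), seed=0, side=side)
        for t, ir in zip(taus, inv_rhos)
    ]


def tau_ladder_1d(n: int = 8) -> np.ndarray:
    """Eight increasing phase amplitudes for the 1D example.

    Capped below tau ~ 3: the instantaneous frequency of exp(i tau sin(20x))
    reaches ~3.2 tau cycles, so larger amplitudes push spectral mass outside
    the 20-coefficient window and the Gaussian fit degenerates.
    """
    return np.linspace(0.5, 2.8, n)
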