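"""Representation and calibration systems on the imaging plane.

A *representation system* {H_k} is the basis in which the unknown field is
recovered (typically Fourier exponentials), while the *calibration system*
{E_m} is the set of fields used to probe the device (typically Gaussian-like
spots).  When the two differ, the change-of-basis matrix H expresses each H_k
approximately as ``H_k = sum_m h_{m,k} E_m + delta_k``; its coefficients are
estimated from Gram matrices of discrete inner products on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .grid import GridSpec, ScalarField


@dataclass
class BasisEval:
    """A system of functions evaluated at the pixel centers of a grid.

    ``values`` has one column per function (pixels x n_functions).
    ``index_meta`` carries per-function metadata: the integer frequency
    pair (k1, k2) for a Fourier system, or the spot center for spots.
    """

    values: np.ndarray
    kind: str  # fourier | spot | wavelet | custom
    grid: GridSpec
    index_meta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("basis values must be a 2D (pixels x functions) array")
        if self.values.shape[0] != self.grid.n_pixels:
            raise ValueError("basis rows do not match grid pixel count")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("basis contains non-finite entries")

    @property
    def n_functions(self) -> int:
        return self.values.shape[1]


def fourier_index_set(K: int) -> np.ndarray:
    """Square integer frequency set I_K for the K-dimensional Fourier basis.

    K must be a perfect square with even root; frequencies run over
    k1, k2 in {-sqrt(K)/2, ..., sqrt(K)/2 - 1}, enumerated row-major with
    k1 as the outer index.
    """
    root = int(round(np.sqrt(K)))
    if root * root != K or root % 2 != 0:
        raise ValueError(f"K={K} is not a perfect even square")
    half = root // 2
    ks = np.arange(-half, half)
    k1, k2 = np.meshgrid(ks, ks, indexing="ij")
    return np.column_stack([k1.ravel(), k2.ravel()])


def fourier_basis(K: int, grid: GridSpec) -> BasisEval:
    """The K-dimensional 2D Fourier system e^{2*pi*i k.x} on the grid."""
    idx = fourier_index_set(K)
    x = grid.centers()
    phase = x @ idx.T  # (pixels, K): k1*x1 + k2*x2
    values = np.exp(2j * np.pi * phase)
    return BasisEval(values, "fourier", grid, idx)


def spot_basis(centers: np.ndarray, width: float, grid: GridSpec) -> BasisEval:
    """Gaussian-like spots exp(-|x - x_m|^2 / (2 width^2)) at given centers."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("no spot centers given")
    if width <= 0:
        raise ValueError("spot width must be positive")
    if not np.all(grid.contains(centers)):
        raise ValueError("spot center outside grid domain")
    x = grid.centers()
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    values = np.exp(-d2 / (2.0 * width**2)).astype(complex)
    return BasisEval(values, "spot", grid, centers)


def spot_lattice(n_side: int, grid: GridSpec, margin: float = 0.05) -> np.ndarray:
    """A square lattice of n_side x n_side spot centers inside the domain."""
    (a1, b1), (a2, b2) = grid.domain
    c1 = np.linspace(a1 + margin * (b1 - a1), b1 - margin * (b1 - a1), n_side)
    c2 = np.linspace(a2 + margin * (b2 - a2), b2 - margin * (b2 - a2), n_side)
    C1, C2 = np.meshgrid(c1, c2, indexing="ij")
    return np.column_stack([C1.ravel(), C2.ravel()])


def wavelet_basis(K: int, grid: GridSpec, levels: int = 2, wavelet: str = "db4") -> BasisEval:
    """K separable orthonormal wavelet functions, coarsest scale first.

    Synthesized by inverse 2D discrete wavelet transform (periodized, hence
    discretely orthonormal) of unit coefficient arrays.  Within a scale the
    order is subband (LL/LH/HL/HH) then raster.  Columns are normalized to
    be orthonormal with respect to the weighted grid inner product.
    """
    n1, n2 = grid.side_counts
    if n1 % (2**levels) or n2 % (2**levels):
        raise ValueError("grid side counts must be divisible by 2^levels")
    if K > grid.n_pixels:
        raise ValueError("K exceeds pixel count")
    w = pywt.Wavelet(wavelet)
    zero = np.zeros((n1, n2))
    coeffs = pywt.wavedec2(zero, w, mode="periodization", level=levels)
    cols = np.empty((grid.n_pixels, K))
    filled = 0
    # enumerate coefficient slots coarsest-first
    slots: list[tuple[int, int | None, int, int]] = []
    approx_shape = coeffs[0].shape
    for i in range(approx_shape[0]):
        for j in range(approx_shape[1]):
            slots.append((0, None, i, j))
    for lev in range(1, levels + 1):
        sub_shape = coeffs[lev][0].shape
        for band in range(3):
            for i in range(sub_shape[0]):
                for j in range(sub_shape[1]):
                    slots.append((lev, band, i, j))
    if K > len(slots):
        raise ValueError("K exceeds the number of wavelet coefficients")
    for lev, band, i, j in slots[:K]:
        c = [np.zeros_like(coeffs[0])] + [
            tuple(np.zeros_like(b) for b in detail) for detail in coeffs[1:]
        ]
        if band is None:
            c[0][i, j] = 1.0
        else:
            cc = [np.array(b) for b in c[lev]]
            cc[band][i, j] = 1.0
            c[lev] = tuple(cc)
        img = pywt.waverec2(c, w, mode="periodization")
        cols[:, filled] = img.ravel()
        filled += 1
    # unit columns under the unweighted dot product -> rescale for the
    # weighted grid inner product
    cols = cols / np.sqrt(grid.weight)
    return BasisEval(cols.astype(complex), "wavelet", grid, np.arange(K))


def gram(basis_a: BasisEval, basis_b: BasisEval) -> np.ndarray:
    """Weighted Gram matrix G[m, m'] = <a_m, b_m'> of two systems on one grid.

    A self-Gram (same object on both sides) is symmetrized so it is exactly
    Hermitian despite floating-point summation order.
    """
    if basis_a.grid != basis_b.grid:
        raise ValueError("bases evaluated on different grids")
    G = basis_a.grid.weight * (basis_a.values.T @ np.conj(basis_b.values))
    if basis_a is basis_b:
        G = (G + np.conj(G.T)) / 2
    return G


@dataclass
class ChangeOfBasis:
    """Coefficients h_{m,k} expressing {H_k} in the calibration system {E_m}.

    ``residual_norms[k]`` is the grid norm of the projection residual
    delta_k = H_k - sum_m h_{m,k} E_m; near-zero residuals certify that the
    representation system lies in the calibration span.
    """

    H: np.ndarray  # (M, K)
    residual_norms: np.ndarray
    gram_condition: float


def change_of_basis(
    E_basis: BasisEval, H_basis: BasisEval, ridge: float = 1e-10
) -> ChangeOfBasis:
    """Estimate the change-of-basis matrix from Gram matrices.

    Solves <H_k, E_m'> = sum_m h_{m,k} <E_m, E_m'> for every m', after
    adding ``ridge * mean(diag)`` to the Gram diagonal for conditioning.
    If the two systems are the same object the result is exactly the
    identity with zero residuals.
    """
    if E_basis.grid != H_basis.grid:
        raise ValueError("bases evaluated on different grids")
    M = E_basis.n_functions
    K = H_basis.n_functions
    if E_basis is H_basis:
        return ChangeOfBasis(np.eye(M, dtype=complex), np.zeros(M), 1.0)
    G = gram(E_basis, E_basis)
    cond = float(np.linalg.cond(G))
    if ridge > 0:
        G = G + (ridge * float(np.mean(np.real(np.diag(G))))) * np.eye(M)
    C = gram(E_basis, H_basis)  # C[m, k] = <E_m, H_k>
    try:
        # equations: conj(C)[m',k] = (G^T h)[m',k]  =>  h = conj(solve(G, C))
        H = np.conj(np.linalg.solve(G, C))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular calibration Gram matrix; increase ridge or reduce M"
        ) from exc
    resid = H_basis.values - E_basis.values @ H
    residual_norms = np.sqrt(E_basis.grid.weight) * np.linalg.norm(resid, axis=0)
    return ChangeOfBasis(H, residual_norms, cond)


def expand(coeffs: np.ndarray, basis: BasisEval) -> ScalarField:
    """Synthesize the field sum_k f_k H_k(x) on the basis grid."""
    coeffs = np.asarray(coeffs).ravel()
    if coeffs.size != basis.n_functions:
        raise ValueError(
            f"{coeffs.size} coefficients for a {basis.n_functions}-function basis"
        )
    return ScalarField(basis.values @ coeffs, basis.grid)


def coefficients(field: ScalarField, basis: BasisEval) -> np.ndarray:
    """Weighted inner products <F, H_k>: exact coefficients for orthonormal bases."""
    return basis.grid.weight * (np.conj(basis.values).T @ field.values)
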