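"""Synthetic multimode-fiber simulator.

A physical fiber maps the optical vector-field at its distal facet to the
proximal facet through a linear integral operator with an unknown
spatially-variant kernel that also mixes the two polarization states.  The
simulator realizes such an operator as a truncated singular-mode expansion:
random band-limited orthonormal input and output modes per polarization, a
decaying singular spectrum and a per-mode 2x2 unitary polarization coupling.
The spectrum decay rate controls how ill-conditioned calibration becomes,
mirroring the accumulation of small singular values in real fibers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, VectorField


@dataclass
class SensorGeometry:
    """Sampling positions y_n of the imaging sensor on the output plane."""

    points: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 1:
            raise ValueError("sensor needs at least one point")

    @property
    def N(self) -> int:
        return len(self.points)


@dataclass
class Measurement:
    """Sensor samples, interleaved [h(y_1), v(y_1), ..., h(y_N), v(y_N)]."""

    values: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()


@dataclass
class KernelModel:
    """Truncated singular expansion of the fiber operator.

    ``input_modes[p]`` / ``output_modes[p]`` are (pixels x n_modes) complex
    matrices per polarization p in {h, v}, orthonormal under the weighted
    grid inner product.  Mode j carries singular value ``singular_values[j]``
    and a 2x2 unitary ``coupling[j]`` acting on the (h, v) mode amplitudes.
    """

    singular_values: np.ndarray
    input_modes: dict
    output_modes: dict
    coupling: np.ndarray  # (n_modes, 2, 2)
    grid: GridSpec
    seed: int

    @property
    def n_modes(self) -> int:
        return len(self.singular_values)


def _bandlimited_modes(rng: np.random.Generator, grid: GridSpec, n_modes: int) -> np.ndarray:
    """Random smooth complex fields, orthonormalized on the grid."""
    n1, n2 = grid.side_counts
    # band limit: enough low frequencies to hold n_modes independent fields
    b = int(np.ceil(np.sqrt(2 * n_modes)))
    b1, b2 = min(b, n1), min(b, n2)
    fields = np.empty((grid.n_pixels, n_modes), dtype=complex)
    for j in range(n_modes):
        spec = np.zeros((n1, n2), dtype=complex)
        block = rng.standard_normal((b1, b2)) + 1j * rng.standard_normal((b1, b2))
        spec[:b1, :b2] = block
        # center the occupied block around frequency zero
        spec = np.roll(spec, (-(b1 // 2), -(b2 // 2)), axis=(0, 1))
        fields[:, j] = np.fft.ifft2(spec).ravel()
    q, _ = np.linalg.qr(fields)
    return q / np.sqrt(grid.weight)  # orthonormal under weighted inner product


def _random_unitary_2x2(rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))


def make_kernel(
    seed: int,
    n_modes: int,
    decay_rate: float,
    coupling_strength: float,
    grid: GridSpec,
) -> KernelModel:
    """Build a seeded fiber operator.

    Singular value j is ``exp(-decay_rate * j / n_modes)``; coupling_strength
    in [0, 1] interpolates each polarization-coupling block between the
    identity (no cross-polarization mixing) and a random unitary (full
    mixing), re-unitarized by polar projection.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > grid.n_pixels:
        raise ValueError("n_modes exceeds pixel count")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    if not 0 <= coupling_strength <= 1:
        raise ValueError("coupling_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    singular_values = np.exp(-decay_rate * np.arange(n_modes) / n_modes)
    input_modes = {
        "h": _bandlimited_modes(rng, grid, n_modes),
        "v": _bandlimited_modes(rng, grid, n_modes),
    }
    output_modes = {
        "h": _bandlimited_modes(rng, grid, n_modes),
        "v": _bandlimited_modes(rng, grid, n_modes),
    }
    coupling = np.empty((n_modes, 2, 2), dtype=complex)
    for j in range(n_modes):
        U = _random_unitary_2x2(rng)
        mix = (1 - coupling_strength) * np.eye(2) + coupling_strength * U
        # polar projection back onto the unitary group
        u, _, vh = np.linalg.svd(mix)
        coupling[j] = u @ vh
    return KernelModel(singular_values, input_modes, output_modes, coupling, grid, seed)


def apply_transform(kernel: KernelModel, field: VectorField) -> VectorField:
    """Apply the fiber operator: mode projection, coupling, scaling, synthesis."""
    if field.grid != kernel.grid:
        raise ValueError("field grid does not match kernel grid")
    w = kernel.grid.weight
    c_h = w * (np.conj(kernel.input_modes["h"]).T @ field.h)
    c_v = w * (np.conj(kernel.input_modes["v"]).T @ field.v)
    c = np.stack([c_h, c_v], axis=1)[..., None]  # (n_modes, 2, 1)
    d = (kernel.coupling @ c)[..., 0] * kernel.singular_values[:, None]
    out_h = kernel.output_modes["h"] @ d[:, 0]
    out_v = kernel.output_modes["v"] @ d[:, 1]
    return VectorField(out_h, out_v, kernel.grid)


def apply_transform_batch(
    kernel: KernelModel, H_mat: np.ndarray, V_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the operator to a batch of fields given as (pixels x M) blocks.

    Column m of ``H_mat``/``V_mat`` holds the h/v component of field m.
    Equivalent to :func:`apply_transform` column by column, as one set of
    matrix products.
    """
    w = kernel.grid.weight
    c_h = w * (np.conj(kernel.input_modes["h"]).T @ H_mat)  # (J, M)
    c_v = w * (np.conj(kernel.input_modes["v"]).T @ V_mat)
    s = kernel.singular_values[:, None]
    C = kernel.coupling
    d_h = s * (C[:, 0, 0][:, None] * c_h + C[:, 0, 1][:, None] * c_v)
    d_v = s * (C[:, 1, 0][:, None] * c_h + C[:, 1, 1][:, None] * c_v)
    return kernel.output_modes["h"] @ d_h, kernel.output_modes["v"] @ d_v


def dense_operator(kernel: KernelModel) -> np.ndarray:
    """Explicit (2 pixels x 2 pixels) matrix of the operator, for small grids.

    Ordering is [all h pixels, all v pixels] on both sides; applying it to
    ``concatenate([F.h, F.v])`` reproduces :func:`apply_transform`.
    """
    w = kernel.grid.weight
    npix = kernel.grid.n_pixels
    Uh, Uv = kernel.input_modes["h"], kernel.input_modes["v"]
    Vh, Vv = kernel.output_modes["h"], kernel.output_modes["v"]
    s = kernel.singular_values
    C = kernel.coupling  # (J, 2, 2)
    G = np.zeros((2 * npix, 2 * npix), dtype=complex)
    G[:npix, :npix] = Vh @ ((s * C[:, 0, 0])[:, None] * (w * np.conj(Uh).T))
    G[:npix, npix:] = Vh @ ((s * C[:, 0, 1])[:, None] * (w * np.conj(Uv).T))
    G[npix:, :npix] = Vv @ ((s * C[:, 1, 0])[:, None] * (w * np.conj(Uh).T))
    G[npix:, npix:] = Vv @ ((s * C[:, 1, 1])[:, None] * (w * np.conj(Uv).T))
    return G


def sensor_from_grid(grid: GridSpec, n_points: int, seed: int | None = None) -> SensorGeometry:
    """Sensor geometry: all pixel centers, or n_points random positions."""
    if seed is None and n_points == grid.n_pixels:
        return SensorGeometry(grid.centers())
    rng = np.random.default_rng(seed)
    (a1, b1), (a2, b2) = grid.domain
    pts = np.column_stack(
        [rng.uniform(a1, b1, n_points), rng.uniform(a2, b2, n_points)]
    )
    return SensorGeometry(pts)


def sample_sensor(
    field: VectorField | np.ndarray,
    geometry: SensorGeometry,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    grid: GridSpec | None = None,
) -> Measurement:
    """Read the field at the sensor points (nearest pixel center) plus noise.

    Noise is i.i.d. circular complex Gaussian with total standard deviation
    ``noise_sigma`` per entry (std ``noise_sigma/sqrt(2)`` in each of the
    real and imaginary parts).  Vector fields are interleaved h, v per point.
    """
    if isinstance(field, VectorField):
        g = field.grid
        idx = g.nearest_pixel(geometry.points)
        vals = np.empty(2 * geometry.N, dtype=complex)
        vals[0::2] = field.h[idx]
        vals[1::2] = field.v[idx]
    else:
        if grid is None:
            raise ValueError("grid required when sampling a raw scalar array")
        idx = grid.nearest_pixel(geometry.points)
        vals = np.asarray(field, dtype=complex).ravel()[idx]
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = (noise_sigma / np.sqrt(2.0)) * (
            rng.standard_normal(vals.shape) + 1j * rng.standard_normal(vals.shape)
        )
        vals = vals + noise
    return Measurement(vals, noise_sigma, seed)
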