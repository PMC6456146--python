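"""Uniform pixel-center grids over the input/output imaging plane.

All fields live on a rectangular domain, by default the unit square
S = [-1/2, 1/2]^2 centered at the origin.  Discrete inner products use the
pixel-center quadrature rule with weight equal to the pixel area, so that
``weight * sum(E * conj(H))`` approximates the L2 inner product
``<E, H> = integral_S E(x) H*(x) dx`` to second order in the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_DOMAIN = ((-0.5, 0.5), (-0.5, 0.5))


@dataclass(frozen=True)
class GridSpec:
    """A uniform lattice of pixel centers on a rectangular domain.

    Parameters
    ----------
    side_counts
        ``(n1, n2)`` pixels along axis 1 (x1) and axis 2 (x2).
    domain
        ``((x1_min, x1_max), (x2_min, x2_max))``; defaults to the unit
        square centered at the origin.
    """

    side_counts: tuple[int, int]
    domain: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_DOMAIN

    def __post_init__(self) -> None:
        n1, n2 = self.side_counts
        if n1 < 1 or n2 < 1:
            raise ValueError(f"side counts must be positive, got {self.side_counts}")
        (a1, b1), (a2, b2) = self.domain
        if not (b1 > a1 and b2 > a2):
            raise ValueError(f"degenerate domain {self.domain}")

    @property
    def n_pixels(self) -> int:
        return self.side_counts[0] * self.side_counts[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.side_counts

    @property
    def pixel_sizes(self) -> tuple[float, float]:
        (a1, b1), (a2, b2) = self.domain
        return ((b1 - a1) / self.side_counts[0], (b2 - a2) / self.side_counts[1])

    @property
    def weight(self) -> float:
        """Quadrature weight: area of one pixel."""
        h1, h2 = self.pixel_sizes
        return h1 * h2

    def axis_centers(self, axis: int) -> np.ndarray:
        a, b = self.domain[axis]
        n = self.side_counts[axis]
        h = (b - a) / n
        return a + h * (np.arange(n) + 0.5)

    def centers(self) -> np.ndarray:
        """All pixel centers as an ``(n_pixels, 2)`` array, x1-major raster order."""
        x1 = self.axis_centers(0)
        x2 = self.axis_centers(1)
        X1, X2 = np.meshgrid(x1, x2, indexing="ij")
        return np.column_stack([X1.ravel(), X2.ravel()])

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        (a1, b1), (a2, b2) = self.domain
        return (
            (pts[:, 0] >= a1) & (pts[:, 0] <= b1) & (pts[:, 1] >= a2) & (pts[:, 1] <= b2)
        )

    def nearest_pixel(self, points: np.ndarray) -> np.ndarray:
        """Flat raster indices of the pixels containing the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(self.contains(pts)):
            raise ValueError("point outside grid domain")
        idx = np.empty((len(pts), 2), dtype=np.intp)
        for axis in range(2):
            a, b = self.domain[axis]
            n = self.side_counts[axis]
            j = np.floor((pts[:, axis] - a) / (b - a) * n).astype(np.intp)
            idx[:, axis] = np.clip(j, 0, n - 1)
        return idx[:, 0] * self.side_counts[1] + idx[:, 1]

    def to_meta(self) -> dict:
        return {"side_counts": list(self.side_counts), "domain": [list(d) for d in self.domain]}

    @classmethod
    def from_meta(cls, meta: dict) -> "GridSpec":
        return cls(
            tuple(int(c) for c in meta["side_counts"]),
            tuple(tuple(float(v) for v in d) for d in meta["domain"]),
        )


def make_grid(side_counts, domain=DEFAULT_DOMAIN) -> GridSpec:
    """Create a :class:`GridSpec` with pixel centers on a uniform lattice."""
    if np.isscalar(side_counts):
        side_counts = (int(side_counts), int(side_counts))
    return GridSpec(tuple(int(c) for c in side_counts), tuple(tuple(map(float, d)) for d in domain))


@dataclass
class ScalarField:
    """Complex scalar field sampled at the pixel centers of a grid."""

    values: np.ndarray  # flat, length grid.n_pixels
    grid: GridSpec
    role: str = "F"  # amplitude "R", phase "P", or complex field "F"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).ravel()
        if self.values.size != self.grid.n_pixels:
            raise ValueError(
                f"field has {self.values.size} samples for a {self.grid.n_pixels}-pixel grid"
            )

    def image(self) -> np.ndarray:
        return self.values.reshape(self.grid.shape)


@dataclass
class VectorField:
    """Two-polarization complex field (horizontal h, vertical v) on a grid."""

    h: np.ndarray
    v: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=complex).ravel()
        self.v = np.asarray(self.v, dtype=complex).ravel()
        if self.h.size != self.grid.n_pixels or self.v.size != self.grid.n_pixels:
            raise ValueError("polarization components do not match the grid")

    def __add__(self, other: "VectorField") -> "VectorField":
        return VectorField(self.h + other.h, self.v + other.v, self.grid)

    def __rmul__(self, scalar: complex) -> "VectorField":
        return VectorField(scalar * self.h, scalar * self.v, self.grid)
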