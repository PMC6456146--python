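"""Polarization-multiplexed calibration and linear-system assembly.

The sensor measures both polarizations of each output, but a scalar
calibration function E_m probes only one input polarization at a time.  To
characterize the full 2x2-coupled operator, each calibration function is
sent through the fiber in two (or three) vector forms that differ only by a
unit-modulus phase factor on the vertical component:

    A_m = [E_m^h; E_m^v],  B_m = [E_m^h; b E_m^v],  C_m = [E_m^h; c E_m^v],

with b = e^{i beta}, beta in (0, 2pi), and optionally c = e^{i gamma} with
c != b and b + c != 2.  Exact linear combinations of these inputs isolate the
single-polarization probes [E_m^h; 0] and [0; E_m^v]; applying the same
combinations to the measured outputs yields the system matrix E of the joint
reconstruction problem g = E H f + eps.  The three-input scheme averages two
independent exposures per combination and is therefore less noise-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber import KernelModel, Measurement, SensorGeometry, apply_transform
from .grid import VectorField
from .representation import BasisEval


@dataclass
class PolarizationScheme:
    """Phase factors of the multiplexed calibration inputs."""

    beta: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.beta < 2 * np.pi:
            raise ValueError("beta must lie in (0, 2*pi)")
        if self.gamma is not None:
            b, c = self.b, self.c
            if np.isclose(c, b):
                raise ValueError("scheme requires c != b")
            if np.isclose(b + c, 2):
                raise ValueError("scheme requires b + c != 2")

    @property
    def b(self) -> complex:
        return np.exp(1j * self.beta)

    @property
    def c(self) -> complex:
        if self.gamma is None:
            raise ValueError("two-input scheme has no gamma")
        return np.exp(1j * self.gamma)

    @property
    def a(self) -> complex:
        if self.gamma is None:
            return 1.0 / (1.0 - self.b)
        return 1.0 / (1.0 - self.b / 2.0 - self.c / 2.0)

    @property
    def three_input(self) -> bool:
        return self.gamma is not None


DEFAULT_SCHEME = PolarizationScheme(beta=np.pi / 2, gamma=np.pi)


def make_polarized_inputs(
    E_h: BasisEval, E_v: BasisEval, scheme: PolarizationScheme
) -> dict:
    """Construct the A_m, B_m (and C_m) vector calibration inputs."""
    if E_h.n_functions != E_v.n_functions:
        raise ValueError("E_h and E_v must have the same cardinality")
    if E_h.grid != E_v.grid:
        raise ValueError("E_h and E_v must share a grid")
    grid = E_h.grid
    M = E_h.n_functions
    out = {"A": [], "B": []}
    if scheme.three_input:
        out["C"] = []
    for m in range(M):
        eh = E_h.values[:, m]
        ev = E_v.values[:, m]
        out["A"].append(VectorField(eh, ev, grid))
        out["B"].append(VectorField(eh, scheme.b * ev, grid))
        if scheme.three_input:
            out["C"].append(VectorField(eh, scheme.c * ev, grid))
    return out


@dataclass
class PolarizedCalibrationSet:
    """Measured outputs of the multiplexed calibration inputs.

    Each output matrix is (2N x M) with rows interleaved h, v per sensor
    point; column m holds the measurement of the corresponding input.
    """

    outputs_A: np.ndarray
    outputs_B: np.ndarray
    scheme: PolarizationScheme
    geometry: SensorGeometry
    outputs_C: np.ndarray | None = None
    E_h: BasisEval | None = None
    E_v: BasisEval | None = None

    def __post_init__(self) -> None:
        shapes = {self.outputs_A.shape, self.outputs_B.shape}
        if self.outputs_C is not None:
            shapes.add(self.outputs_C.shape)
        if len(shapes) != 1:
            raise ValueError("calibration output blocks must share one shape")
        if self.outputs_A.shape[0] != 2 * self.geometry.N:
            raise ValueError("output rows must equal 2N")

    @property
    def M(self) -> int:
        return self.outputs_A.shape[1]

    @property
    def N(self) -> int:
        return self.geometry.N


def measure_calibration(
    inputs: dict,
    kernel: KernelModel,
    geometry: SensorGeometry,
    scheme: PolarizationScheme,
    noise_sigma: float = 0.0,
    seed: int = 0,
    E_h: BasisEval | None = None,
    E_v: BasisEval | None = None,
) -> PolarizedCalibrationSet:
    """Send every calibration input through the fiber and sample the sensor.

    Each column is a separate exposure; noise entries are i.i.d. across the
    whole set and deterministic for a fixed ``seed``.
    """
    from .fiber import apply_transform_batch

    idx = None
    blocks = {}
    rng = np.random.default_rng(seed)
    for name in ("A", "B", "C"):
        if name not in inputs:
            continue
        fields = inputs[name]
        H_mat = np.column_stack([f.h for f in fields])
        V_mat = np.column_stack([f.v for f in fields])
        out_h, out_v = apply_transform_batch(kernel, H_mat, V_mat)
        if idx is None:
            idx = kernel.grid.nearest_pixel(geometry.points)
        block = np.empty((2 * geometry.N, len(fields)), dtype=complex)
        block[0::2] = out_h[idx]
        block[1::2] = out_v[idx]
        if noise_sigma > 0:
            # independent circular complex Gaussian noise per exposure entry
            block = block + (noise_sigma / np.sqrt(2.0)) * (
                rng.standard_normal(block.shape) + 1j * rng.standard_normal(block.shape)
            )
        blocks[name] = block
    return PolarizedCalibrationSet(
        outputs_A=blocks["A"],
        outputs_B=blocks["B"],
        outputs_C=blocks.get("C"),
        scheme=scheme,
        geometry=geometry,
        E_h=E_h,
        E_v=E_v,
    )


@dataclass
class LinearSystem:
    """The assembled measurement system g = E H f + eps."""

    E: np.ndarray
    H: np.ndarray | None  # None means identity
    g: np.ndarray
    mode: str  # scalar | vector2 | vector3 | single_h | single_v
    _EH: np.ndarray | None = None

    @property
    def EH(self) -> np.ndarray:
        """The product E @ H, materialized on first use."""
        if self._EH is None:
            self._EH = self.E if self.H is None else self.E @ self.H
        return self._EH

    @property
    def shape(self) -> tuple[int, int]:
        return self.EH.shape


def _block_H(H_h: np.ndarray | None, H_v: np.ndarray | None, M: int) -> np.ndarray | None:
    if H_h is None and H_v is None:
        return None
    Hh = np.eye(M, dtype=complex) if H_h is None else np.asarray(H_h)
    Hv = np.eye(M, dtype=complex) if H_v is None else np.asarray(H_v)
    top = np.hstack([Hh, np.zeros((Hh.shape[0], Hv.shape[1]))])
    bot = np.hstack([np.zeros((Hv.shape[0], Hh.shape[1])), Hv])
    return np.vstack([top, bot])


def assemble_system(
    calib: PolarizedCalibrationSet,
    g: Measurement | np.ndarray,
    H_h: np.ndarray | None = None,
    H_v: np.ndarray | None = None,
) -> LinearSystem:
    """Assemble the joint two-polarization system from calibration outputs.

    With two input sets the system matrix is
    ``E = [a*(A - b* B), a (A - B)]``; with three it is
    ``E = [a*(A - (b*/2) B - (c*/2) C), a (A - B/2 - C/2)]``.
    The first M columns multiply the horizontal coefficients f^h, the last M
    the vertical coefficients f^v.
    """
    gv = g.values if isinstance(g, Measurement) else np.asarray(g, dtype=complex).ravel()
    if gv.size != 2 * calib.N:
        raise ValueError(f"g has length {gv.size}, expected 2N = {2 * calib.N}")
    s = calib.scheme
    A, B, C = calib.outputs_A, calib.outputs_B, calib.outputs_C
    # keep the blocks' precision (large calibrations may use complex64)
    dt = A.dtype
    a, b = dt.type(s.a), dt.type(s.b)
    if C is None:
        Eh_block = np.conj(a) * (A - np.conj(b) * B)
        Ev_block = a * (A - B)
        mode = "vector2"
    else:
        c = dt.type(s.c)
        Eh_block = A - (np.conj(b) / 2) * B
        Eh_block -= (np.conj(c) / 2) * C
        Eh_block *= np.conj(a)
        Ev_block = A - dt.type(0.5) * B
        Ev_block -= dt.type(0.5) * C
        Ev_block *= a
        mode = "vector3"
    E = np.hstack([Eh_block, Ev_block])
    del Eh_block, Ev_block
    H = _block_H(H_h, H_v, calib.M)
    if H is not None and H.shape[0] != E.shape[1]:
        raise ValueError("H block shape incompatible with E")
    return LinearSystem(E, H, gv, mode)


def assemble_scalar_system(
    outputs: np.ndarray, g: Measurement | np.ndarray, H: np.ndarray | None = None
) -> LinearSystem:
    """Scalar (single-polarization device) system: E[n, m] = tilde{E}_m(y_n)."""
    gv = g.values if isinstance(g, Measurement) else np.asarray(g, dtype=complex).ravel()
    E = np.asarray(outputs)
    if gv.size != E.shape[0]:
        raise ValueError("g length does not match output rows")
    if H is not None and np.asarray(H).shape[0] != E.shape[1]:
        raise ValueError("H rows must equal M")
    return LinearSystem(E, H, gv, "scalar")


def assemble_single_polarization_system(
    calib: PolarizedCalibrationSet,
    which: str,
    g_single: Measurement | np.ndarray,
    H: np.ndarray | None = None,
) -> LinearSystem:
    """Single-polarization variant: only one polarization's sensor rows.

    The horizontal probe outputs are ``a*(A - (b*/2)B - (c*/2)C)`` restricted
    to the even (h) interleaved rows; the vertical ones ``a(A - B/2 - C/2)``
    restricted to the odd (v) rows.  Two-input schemes use the corresponding
    two-term combinations.
    """
    if which not in ("h", "v"):
        raise ValueError("which must be 'h' or 'v'")
    gv = (
        g_single.values
        if isinstance(g_single, Measurement)
        else np.asarray(g_single, dtype=complex).ravel()
    )
    if gv.size != calib.N:
        raise ValueError("single-polarization g must have length N")
    s = calib.scheme
    A, B, C = calib.outputs_A, calib.outputs_B, calib.outputs_C
    a, b = s.a, s.b
    if C is None:
        comb = np.conj(a) * (A - np.conj(b) * B) if which == "h" else a * (A - B)
    else:
        c = s.c
        comb = (
            np.conj(a) * (A - (np.conj(b) / 2) * B - (np.conj(c) / 2) * C)
            if which == "h"
            else a * (A - B / 2 - C / 2)
        )
    rows = slice(0, None, 2) if which == "h" else slice(1, None, 2)
    E = comb[rows]
    if H is not None and np.asarray(H).shape[0] != E.shape[1]:
        raise ValueError("H rows must equal M")
    return LinearSystem(E, H, gv, f"single_{which}")
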