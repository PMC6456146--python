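"""Inversion strategies for the calibrated measurement system g = E H f + eps.

Four approaches are provided, in increasing order of robustness on
ill-conditioned systems:

* ``naive``  — phase conjugation, f = (EH)^H g; exact only when the system
  has orthonormal columns.
* ``lstsq``  — unregularized least squares.
* ``tikhonov`` (l2) — ridge-regularized closed form
  f = ((EH)^H EH + lambda I)^{-1} (EH)^H g.
* ``l1``     — complex LASSO, argmin 1/2 ||g - EH f||_2^2 + lambda ||f||_1,
  solved by accelerated proximal gradient (FISTA) with the complex
  soft-threshold prox acting on the modulus and preserving the phase.

Note the l1 objective uses the *squared* data-fidelity term.  The same
solution path is traversed by the unsquared form under a reparameterization
of lambda, and the squared form is what fast iterative shrinkage solvers
minimize; lambda values are therefore not transferable between the two
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import LinearSystem
from .grid import VectorField
from .representation import BasisEval, expand


@dataclass
class SolveResult:
    """Recovered coefficient vector and solver diagnostics."""

    coeffs: np.ndarray
    method: str
    lam: float = 0.0
    iterations: int = 0
    final_residual: float = 0.0
    converged: bool = True

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """Split a joint vector solution into (f_h, f_v)."""
        K2 = self.coeffs.size
        if K2 % 2:
            raise ValueError("coefficient vector has odd length; not a joint solution")
        return self.coeffs[: K2 // 2], self.coeffs[K2 // 2 :]


def _residual(A: np.ndarray, f: np.ndarray, g: np.ndarray) -> float:
    return float(np.linalg.norm(g - A @ f))


def solve_naive(system: LinearSystem) -> SolveResult:
    """Phase conjugation: f = (EH)^H g."""
    A = system.EH
    f = np.conj(A).T @ system.g
    return SolveResult(f, "naive", 0.0, 0, _residual(A, f, system.g))


def solve_least_squares(system: LinearSystem) -> SolveResult:
    """Unregularized least squares; requires EH to have full column rank."""
    A = system.EH
    f, _, rank, _ = np.linalg.lstsq(A, system.g, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"system matrix is rank deficient (rank {rank} < {A.shape[1]} columns); "
            "use Tikhonov or l1 regularization"
        )
    return SolveResult(f, "lstsq", 0.0, 0, _residual(A, f, system.g))


def solve_tikhonov(system: LinearSystem, lam: float) -> SolveResult:
    """Ridge (l2) regularization: f = ((EH)^H EH + lam I)^{-1} (EH)^H g."""
    if lam <= 0:
        raise ValueError("Tikhonov lambda must be positive")
    A = system.EH
    K = A.shape[1]
    AhA = np.conj(A).T @ A + lam * np.eye(K)
    f = np.linalg.solve(AhA, np.conj(A).T @ system.g)
    return SolveResult(f, "tikhonov", lam, 0, _residual(A, f, system.g))


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Complex soft-threshold: shrink the modulus by t, keep the phase."""
    mag = np.abs(z)
    scale = np.maximum(mag - t, 0.0)
    out = np.zeros_like(z)
    nz = mag > 0
    out[nz] = z[nz] * (scale[nz] / mag[nz])
    return out


def operator_norm(A: np.ndarray, n_iter: int = 50, seed: int = 0) -> float:
    """Largest singular value of A, by power iteration on A^H A."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(A.shape[1]) + 1j * rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        w = np.conj(A).T @ (A @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
    return float(np.sqrt(np.linalg.norm(np.conj(A).T @ (A @ v))))


def solve_l1(
    system: LinearSystem,
    lam: float,
    max_iter: int = 2000,
    tol: float = 1e-6,
    step: float | None = None,
    lam_relative: bool = False,
) -> SolveResult:
    """Complex LASSO via FISTA.

    With ``lam_relative=True`` the threshold is ``lam * ||(EH)^H g||_inf``,
    which rescales with the data; otherwise lambda is absolute.  Stops when
    the relative coefficient change drops below ``tol`` or after
    ``max_iter`` iterations (flagged, not raised).
    """
    if lam < 0:
        raise ValueError("l1 lambda must be >= 0")
    A = system.EH
    g = system.g
    Ahg = np.conj(A).T @ g
    if lam_relative:
        lam = lam * float(np.max(np.abs(Ahg)))
    if step is None:
        L = operator_norm(A) ** 2
        step = 0.99 / L if L > 0 else 1.0
    f = np.zeros(A.shape[1], dtype=complex)
    y = f.copy()
    t_mom = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = np.conj(A).T @ (A @ y) - Ahg
        f_new = soft_threshold(y - step * grad, step * lam)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = f_new + ((t_mom - 1.0) / t_new) * (f_new - f)
        denom = np.linalg.norm(f_new)
        change = np.linalg.norm(f_new - f) / denom if denom > 0 else np.linalg.norm(f_new - f)
        f, t_mom = f_new, t_new
        if change < tol:
            converged = True
            break
    return SolveResult(f, "l1", lam, it, _residual(A, f, g), converged)


_SOLVERS = {
    "naive": solve_naive,
    "lstsq": solve_least_squares,
    "l2": solve_tikhonov,
    "tikhonov": solve_tikhonov,
    "l1": solve_l1,
}


def solve(system: LinearSystem, method: str, lam: float = 0.0, **kwargs) -> SolveResult:
    """Dispatch to one of the four inversion strategies."""
    if method not in _SOLVERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_SOLVERS)}")
    if method in ("naive", "lstsq"):
        return _SOLVERS[method](system)
    return _SOLVERS[method](system, lam, **kwargs)


def reconstruct(
    system: LinearSystem,
    method: str,
    basis_h: BasisEval,
    basis_v: BasisEval,
    lam: float = 0.0,
    **kwargs,
) -> tuple[SolveResult, VectorField]:
    """Solve the joint system and expand both polarizations on the grid."""
    if basis_h.n_functions != basis_v.n_functions:
        raise ValueError("h and v representation bases must share cardinality")
    result = solve(system, method, lam, **kwargs)
    f_h, f_v = result.split()
    if f_h.size != basis_h.n_functions:
        raise ValueError("solution length does not match basis cardinality")
    field_h = expand(f_h, basis_h)
    field_v = expand(f_v, basis_v)
    return result, VectorField(field_h.values, field_v.values, basis_h.grid)


def cross_validate_lambda(
    system: LinearSystem,
    method: str,
    lambdas,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    **kwargs,
) -> float:
    """Grid search with a random holdout of measurement rows.

    Optional helper: fits on the retained rows for each candidate lambda and
    returns the one with the smallest holdout residual.
    """
    rng = np.random.default_rng(seed)
    n = system.EH.shape[0]
    mask = rng.random(n) < holdout_fraction
    if mask.all() or not mask.any():
        raise ValueError("degenerate holdout split")
    A = system.EH
    train = LinearSystem(A[~mask], None, system.g[~mask], system.mode)
    best_lam, best_err = None, np.inf
    for lam in lambdas:
        res = solve(train, method, lam, **kwargs)
        err = float(np.linalg.norm(system.g[mask] - A[mask] @ res.coeffs))
        if err < best_err:
            best_lam, best_err = lam, err
    return best_lam
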