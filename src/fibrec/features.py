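"""Fourier-decay scattering features and group statistics.

The decay of a field's Fourier coefficients quantifies how strongly its
phase oscillates.  The pipeline: approximate the Fourier transform from the
first 20 (or 20x20) Fourier coefficients by Whittaker-Shannon sinc
interpolation, fit a Gaussian to its modulus on [-10, 10) (separable and
axis-aligned in 2D), and report the fitted standard deviation sigma (1D) or
sigma1 + sigma2 (2D).  Because the modulus of the Fourier transform is
shift-invariant, so is the feature.  Per-sample features are averaged per
tissue area and compared between classes with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .tissue import fourier_coeffs_2d

FIT_WINDOW = (-10.0, 10.0)
FIT_STEP_1D = 0.1
FIT_STEP_2D = 0.25


@dataclass
class GaussianFit:
    """Fitted Gaussian parameters; sigma has 1 (1D) or 2 (2D) components."""

    amplitude: float
    center: np.ndarray
    sigma: np.ndarray
    fit_rmse: float

    @property
    def sigma_sum(self) -> float:
        return float(np.sum(self.sigma))


@dataclass
class TestResult:
    """Welch two-sample t-test with Welch-Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def sinc_interpolate(coeffs: np.ndarray, index_meta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Whittaker-Shannon interpolation sum_k f_k sinc(w - k) of the FT.

    1D when ``index_meta`` is a vector of integer frequencies; 2D
    (separably) when it is an (n, 2) index array, in which case ``w`` must
    be (m, 2) evaluation frequencies.  Exact at integer frequencies:
    ``sinc`` vanishes at nonzero integers and equals 1 at 0.
    """
    coeffs = np.asarray(coeffs).ravel()
    idx = np.asarray(index_meta)
    w = np.asarray(w, dtype=float)
    if idx.ndim == 1:
        return np.sinc(np.subtract.outer(w, idx.astype(float))) @ coeffs
    if idx.shape[1] != 2:
        raise ValueError("2D index_meta must be (n, 2)")
    w2 = np.atleast_2d(w)
    S = np.sinc(np.subtract.outer(w2[:, 0], idx[:, 0].astype(float))) * np.sinc(
        np.subtract.outer(w2[:, 1], idx[:, 1].astype(float))
    )
    out = S @ coeffs
    return out if w.ndim > 1 else out[0]


def interpolated_ft_grid_2d(
    coeffs: np.ndarray, index_meta: np.ndarray, step: float = FIT_STEP_2D
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|FT| on the regular fitting lattice over [-10, 10)^2, separably.

    Returns ``(w1, w2, ft)`` with ``ft`` of shape (len(w1), len(w2)).
    """
    idx = np.asarray(index_meta)
    coeffs = np.asarray(coeffs).ravel()
    w = np.arange(FIT_WINDOW[0], FIT_WINDOW[1], step)
    k1 = np.unique(idx[:, 0])
    k2 = np.unique(idx[:, 1])
    C = np.zeros((k1.size, k2.size), dtype=complex)
    i1 = np.searchsorted(k1, idx[:, 0])
    i2 = np.searchsorted(k2, idx[:, 1])
    C[i1, i2] = coeffs
    S1 = np.sinc(np.subtract.outer(w, k1.astype(float)))
    S2 = np.sinc(np.subtract.outer(w, k2.astype(float)))
    return w, w, S1 @ C @ S2.T


def _moment_init(w: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Center and sigma from the first two moments of normalized values."""
    v = np.clip(v, 0, None)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate (non-positive) profile")
    c = float((w * v).sum() / total)
    var = float(((w - c) ** 2 * v).sum() / total)
    return c, max(np.sqrt(var), 1e-3)


def fit_gaussian_1d(values: np.ndarray, w: np.ndarray | None = None) -> GaussianFit:
    """Fit a exp(-(w - c)^2 / (2 sigma^2)) to a nonnegative profile.

    Damped nonlinear least squares with moment-based initialization;
    positivity of sigma is enforced by optimizing log sigma.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(values) == 0:
        raise ValueError("flat input cannot be fitted")
    if w is None:
        w = np.arange(FIT_WINDOW[0], FIT_WINDOW[1], FIT_STEP_1D)
    w = np.asarray(w, dtype=float).ravel()
    c0, s0 = _moment_init(w, values)
    a0 = float(values.max())

    def resid(p):
        a, c, logs = p
        return a * np.exp(-((w - c) ** 2) / (2 * np.exp(2 * logs))) - values

    sol = optimize.least_squares(resid, [a0, c0, np.log(s0)], method="lm")
    a, c, logs = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return GaussianFit(float(a), np.array([c]), np.array([np.exp(logs)]), rmse)


def fit_gaussian_2d(
    values: np.ndarray, w1: np.ndarray | None = None, w2: np.ndarray | None = None
) -> GaussianFit:
    """Axis-aligned 2D Gaussian fit a exp(-sum_i (w_i - c_i)^2/(2 sigma_i^2))."""
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValueError("expected a 2D array of |FT| values")
    if np.ptp(V) == 0:
        raise ValueError("flat input cannot be fitted")
    if w1 is None:
        w1 = np.arange(FIT_WINDOW[0], FIT_WINDOW[1], FIT_STEP_2D)
    if w2 is None:
        w2 = np.arange(FIT_WINDOW[0], FIT_WINDOW[1], FIT_STEP_2D)
    c1_0, s1_0 = _moment_init(np.asarray(w1), V.sum(axis=1))
    c2_0, s2_0 = _moment_init(np.asarray(w2), V.sum(axis=0))
    a0 = float(V.max())
    W1 = np.asarray(w1)[:, None]
    W2 = np.asarray(w2)[None, :]

    def resid(p):
        a, c1, c2, l1, l2 = p
        model = a * np.exp(
            -((W1 - c1) ** 2) / (2 * np.exp(2 * l1)) - ((W2 - c2) ** 2) / (2 * np.exp(2 * l2))
        )
        return (model - V).ravel()

    sol = optimize.least_squares(
        resid, [a0, c1_0, c2_0, np.log(s1_0), np.log(s2_0)], method="lm"
    )
    a, c1, c2, l1, l2 = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return GaussianFit(
        float(a), np.array([c1, c2]), np.exp([l1, l2]), rmse
    )


def decay_feature(
    field_or_coeffs: np.ndarray,
    index_meta: np.ndarray | None = None,
    n_coeffs: int = 20,
) -> GaussianFit:
    """The sigma1 + sigma2 decay feature of a 2D field or coefficient set.

    Given a complex field on a uniform grid, its first n_coeffs x n_coeffs
    Fourier coefficients are computed by quadrature; given precomputed
    coefficients, ``index_meta`` must carry their (k1, k2) indices.  The
    coefficient moduli are sinc-interpolated onto the fitting lattice and
    fitted by an axis-aligned Gaussian; ``.sigma_sum`` is the scalar
    feature.  Interpolating the moduli (rather than taking the modulus of
    the interpolated transform) makes the feature exactly invariant to
    whole-pixel shifts and to global phase offsets of the field.
    """
    arr = np.asarray(field_or_coeffs)
    if index_meta is None:
        k, f = fourier_coeffs_2d(arr, n_coeffs)
    else:
        k, f = np.asarray(index_meta), arr.ravel()
    # interpolate the coefficient moduli: the modulus lattice is exactly
    # invariant under whole-pixel shifts of the field, so the feature is too
    w1, w2, ft = interpolated_ft_grid_2d(np.abs(f).astype(complex), k)
    return fit_gaussian_2d(np.abs(ft.real), w1, w2)


def unwrap_phase_2d(wrapped: np.ndarray) -> np.ndarray:
    """Recover a continuous phase surface from values modulo 2 pi.

    Reliability-ordered unwrapping; the output differs from the input by
    integer multiples of 2 pi at every pixel, and recovers a smooth true
    phase (gradient below pi per pixel step) up to one global 2 pi offset.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    return np.asarray(_skimage_unwrap(wrapped))


def welch_t_test(group_a, group_b) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=a.size,
        n_b=b.size,
    )


def feature_table(records: list[dict]) -> pd.DataFrame:
    """Assemble per-sample feature records into a tidy table.

    Expected keys per record: area, subimage, polarization, sigma1, sigma2,
    feature, label.
    """
    df = pd.DataFrame.from_records(records)
    required = {"area", "subimage", "polarization", "feature", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing feature-record columns: {sorted(missing)}")
    return df


def group_analysis(
    table: pd.DataFrame, combine_polarizations: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-area mean features and Welch tests between the two class labels.

    Per-area means are taken over sub-images within each (area,
    polarization).  When combining polarizations, each polarization's area
    means are z-scored by the overall mean/std across all areas, the two
    z-scores are averaged per area, and a single Welch test compares the
    classes on the combined score; otherwise one test per polarization.
    """
    per_area = (
        table.groupby(["area", "polarization", "label"], as_index=False)["feature"].mean()
    )
    labels = sorted(table["label"].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two class labels, got {labels}")
    tests: dict[str, TestResult] = {}
    if combine_polarizations:
        pols = sorted(per_area["polarization"].unique())
        if len(pols) < 2:
            raise ValueError("combining requires both polarizations")
        z_by_area = []
        for pol in pols:
            sub = per_area[per_area["polarization"] == pol].set_index("area")
            z = (sub["feature"] - sub["feature"].mean()) / sub["feature"].std(ddof=1)
            z_by_area.append(z)
        combined = pd.concat(z_by_area, axis=1).mean(axis=1)
        lab = per_area[per_area["polarization"] == pols[0]].set_index("area")["label"]
        tests["combined"] = welch_t_test(
            combined[lab == labels[0]], combined[lab == labels[1]]
        )
    else:
        for pol, sub in per_area.groupby("polarization"):
            tests[str(pol)] = welch_t_test(
                sub.loc[sub["label"] == labels[0], "feature"],
                sub.loc[sub["label"] == labels[1], "feature"],
            )
    return per_area, tests
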