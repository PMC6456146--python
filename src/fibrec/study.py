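"""End-to-end synthetic study: calibrate, image phantoms, reconstruct, test.

Mirrors the experimental pipeline at desk scale: a seeded fiber operator is
calibrated with polarization-multiplexed Gaussian spots, simulated tissue
phantoms from two (tau, rho) categories are imaged through it, Fourier
coefficients are recovered jointly for both polarizations by regularized
inversion, the sigma1 + sigma2 decay feature is extracted per sub-image,
averaged per area, and the two classes are compared with Welch's t-test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import fiber, representation as rep, solvers, tissue
from .config import StudyConfig
from .features import decay_feature, feature_table, group_analysis
from .grid import VectorField, make_grid

log = logging.getLogger(__name__)


def build_calibration(cfg: StudyConfig):
    """Kernel, spot calibration set and sensor geometry from a config."""
    grid = make_grid(cfg.grid_side)
    kernel = fiber.make_kernel(
        cfg.kernel.seed,
        cfg.kernel.n_modes,
        cfg.kernel.decay_rate,
        cfg.kernel.coupling_strength,
        grid,
    )
    n_side = int(round(np.sqrt(cfg.calibration.M)))
    if n_side * n_side != cfg.calibration.M:
        raise ValueError("calibration M must be a perfect square for the spot lattice")
    centers = rep.spot_lattice(n_side, grid)
    spots = rep.spot_basis(centers, cfg.calibration.spot_width, grid)
    scheme = cal.PolarizationScheme(cfg.calibration.beta, cfg.calibration.gamma)
    geometry = fiber.sensor_from_grid(
        grid, cfg.calibration.sensor_points, seed=cfg.calibration.sensor_seed
    )
    inputs = cal.make_polarized_inputs(spots, spots, scheme)
    t0 = time.perf_counter()
    calib = cal.measure_calibration(
        inputs,
        kernel,
        geometry,
        scheme,
        noise_sigma=cfg.calibration.noise_sigma,
        seed=cfg.calibration.sensor_seed,
        E_h=spots,
        E_v=spots,
    )
    log.info("calibration: M=%d, N=%d, %.2fs", calib.M, calib.N, time.perf_counter() - t0)
    return grid, kernel, spots, calib, geometry


def representation_basis(cfg: StudyConfig, grid):
    if cfg.reconstruction.basis == "fourier":
        return rep.fourier_basis(cfg.reconstruction.K, grid)
    if cfg.reconstruction.basis == "wavelet":
        return rep.wavelet_basis(cfg.reconstruction.K, grid)
    raise ValueError(f"unsupported study basis {cfg.reconstruction.basis!r}")


def run_study(cfg: StudyConfig, write_outputs: bool = True):
    """Execute the full pipeline; returns (feature table, tests, report)."""
    out_dir = Path(cfg.output_dir)
    grid, kernel, spots, calib, geometry = build_calibration(cfg)

    H_basis = representation_basis(cfg, grid)
    cob = rep.change_of_basis(spots, H_basis)
    log.info("change of basis: Gram condition %.3g, max residual %.3g",
             cob.gram_condition, float(cob.residual_norms.max()))

    cats = tissue.default_categories(side=cfg.grid_side)
    chosen = [cats[i - 1] for i in cfg.phantoms.categories]
    labels = ["healthy", "lesion"]
    if len(chosen) != 2:
        raise ValueError("study needs exactly two phantom categories")

    records = []
    seed_counter = cfg.phantoms.seed
    t0 = time.perf_counter()
    for label, params in zip(labels, chosen):
        for area in range(cfg.phantoms.areas_per_class):
            for sub in range(cfg.phantoms.subimages_per_area):
                comp = {}
                for pol in ("h", "v"):
                    p = dataclasses.replace(params, seed=seed_counter)
                    comp[pol] = tissue.make_tissue_image(p, seed_amp=seed_counter + 1)
                    seed_counter += 2
                field = VectorField(comp["h"].values, comp["v"].values, grid)
                out = fiber.apply_transform(kernel, field)
                g = fiber.sample_sensor(
                    out, geometry, cfg.reconstruction.noise_sigma, seed=seed_counter
                )
                seed_counter += 1
                system = cal.assemble_system(calib, g, cob.H, cob.H)
                kwargs = {}
                if cfg.reconstruction.method == "l1":
                    kwargs["lam_relative"] = cfg.reconstruction.lam_relative
                res = solvers.solve(
                    system, cfg.reconstruction.method, cfg.reconstruction.lam, **kwargs
                )
                f_h, f_v = res.split()
                for pol, f in (("h", f_h), ("v", f_v)):
                    fit = decay_feature(f, index_meta=H_basis.index_meta)
                    records.append(
                        {
                            "area": f"{label}_{area + 1}",
                            "subimage": sub + 1,
                            "polarization": pol,
                            "sigma1": float(fit.sigma[0]),
                            "sigma2": float(fit.sigma[1]),
                            "feature": fit.sigma_sum,
                            "label": label,
                        }
                    )
    log.info("imaging + reconstruction: %d records, %.2fs",
             len(records), time.perf_counter() - t0)

    table = feature_table(records)
    per_area, tests = group_analysis(table)
    _, combined = group_analysis(table, combine_polarizations=True)
    tests.update(combined)

    report = {
        "n_records": len(records),
        "system_shape": list(system.shape),
        "tests": {
            name: {"t": r.t, "df": r.df, "p": r.p, "mean_healthy": r.mean_a,
                   "mean_lesion": r.mean_b}
            for name, r in tests.items()
        },
    }
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "feature_table.tsv", sep="\t", index=False)
        per_area.to_csv(out_dir / "per_area_means.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return table, tests, report


def category_feature_means(
    side: int = 200, n_seeds: int = 20, seed: int = 1
) -> np.ndarray:
    """Mean decay feature per (tau, rho) category, paired over seeds.

    For each seed, all six categories share the same amplitude draw and the
    same phase-noise realization (only the smoothing and rescaling differ),
    so the category contrast is not masked by draw-to-draw amplitude
    variability; the mean over seeds is returned per category.
    """
    from .features import decay_feature

    cats = tissue.default_categories(side=side)
    means = np.zeros(len(cats))
    base = int(seed) % 2**20
    for s in range(n_seeds):
        for j, cat in enumerate(cats):
            p = dataclasses.replace(cat, seed=base + s)
            F = tissue.make_tissue_image(p, seed_amp=base + 500000 + s)
            means[j] += decay_feature(F.image()).sigma_sum
    return means / n_seeds


def feature_power_study(
    n_reps: int = 100,
    side: int = 128,
    n_areas: int = 6,
    n_sub: int = 6,
    categories: tuple[int, int] = (2, 5),
    alpha: float = 0.05,
    seed: int = 1,
) -> float:
    """Fraction of repetitions in which the two-class Welch test rejects.

    Each repetition simulates ``n_areas`` healthy areas from the first
    category and ``n_areas`` lesion areas from the second, with ``n_sub``
    independently seeded sub-images per area, extracts the decay feature
    per sub-image, averages per area and applies Welch's t-test to the
    per-area means.
    """
    from .features import decay_feature, welch_t_test

    cats = tissue.default_categories(side=side)
    chosen = [cats[c - 1] for c in categories]
    rejections = 0
    counter = int(seed) % 2**20
    for _ in range(n_reps):
        means = {0: [], 1: []}
        for ci, cat in enumerate(chosen):
            for _area in range(n_areas):
                feats = []
                for _sub in range(n_sub):
                    p = dataclasses.replace(cat, seed=counter)
                    F = tissue.make_tissue_image(p, seed_amp=counter + 1)
                    counter += 2
                    feats.append(decay_feature(F.image()).sigma_sum)
                means[ci].append(float(np.mean(feats)))
        res = welch_t_test(means[0], means[1])
        rejections += res.p < alpha
    return rejections / n_reps
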