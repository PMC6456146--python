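import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import fibrec as fr


class TestSincInterpolate:
    def test_integer_frequencies_return_coefficients(self):
        rng = np.random.default_rng(0)
        k = np.arange(-10, 10)
        f = rng.standard_normal(20) + 1j * rng.standard_normal(20)
        vals = fr.sinc_interpolate(f, k, k.astype(float))
        assert np.abs(vals - f).max() < 1e-12

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(1)
        k = np.arange(-5, 5)
        f1 = rng.standard_normal(10) + 0j
        f2 = rng.standard_normal(10) + 0j
        w = np.linspace(-4.3, 4.3, 17)
        lhs = fr.sinc_interpolate(2 * f1 - 3j * f2, k, w)
        rhs = 2 * fr.sinc_interpolate(f1, k, w) - 3j * fr.sinc_interpolate(f2, k, w)
        assert np.abs(lhs - rhs).max() < 1e-12

    def test_agrees_with_truncated_series_transform_oracle(self):
        """sinc interpolation = continuous FT of the truncated Fourier series."""
        rng = np.random.default_rng(2)
        k = np.arange(-10, 10)
        f = rng.standard_normal(20) + 1j * rng.standard_normal(20)
        for w in (0.35, -3.6, 7.25):
            val = fr.sinc_interpolate(f, k, np.array([w]))[0]

            def field(x):
                return np.sum(f * np.exp(2j * np.pi * k * x))

            re = integrate.quad(
                lambda x: np.real(field(x) * np.exp(-2j * np.pi * w * x)),
                -0.5, 0.5, limit=400,
            )[0]
            im = integrate.quad(
                lambda x: np.imag(field(x) * np.exp(-2j * np.pi * w * x)),
                -0.5, 0.5, limit=400,
            )[0]
            assert abs(val - (re + 1j * im)) < 1e-8

    def test_2d_separable_at_lattice_points(self):
        rng = np.random.default_rng(3)
        idx = fr.fourier_index_set(16)
        f = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        vals = fr.sinc_interpolate(f, idx, idx.astype(float))
        assert np.abs(vals - f).max() < 1e-12


class TestFitGaussian1D:
    def test_exact_model_recovered(self):
        w = np.arange(-10, 10, 0.1)
        truth = 2.0 * np.exp(-((w - 1.0) ** 2) / (2 * 3.0**2))
        fit = fr.fit_gaussian_1d(truth, w)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.center[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.sigma[0] == pytest.approx(3.0, abs=1e-6)

    def test_sigma_invariant_to_positive_scaling(self):
        w = np.arange(-10, 10, 0.1)
        vals = 1.3 * np.exp(-(w**2) / (2 * 2.2**2)) + 0.01
        s1 = fr.fit_gaussian_1d(vals, w).sigma[0]
        s2 = fr.fit_gaussian_1d(17.0 * vals, w).sigma[0]
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_sigma_robust_to_small_noise(self):
        rng = np.random.default_rng(4)
        w = np.arange(-10, 10, 0.1)
        truth = 1.0 * np.exp(-(w**2) / (2 * 2.5**2))
        noisy = truth + 0.01 * rng.standard_normal(w.size)
        fit = fr.fit_gaussian_1d(noisy, w)
        assert fit.sigma[0] == pytest.approx(2.5, rel=0.02)

    def test_flat_input_rejected(self):
        with pytest.raises(ValueError):
            fr.fit_gaussian_1d(np.ones(50))

    def test_higher_phase_amplitude_widens_spectrum(self):
        sigmas = {}
        w = np.arange(-10, 10, 0.1)
        for tau in (0.5, 3.0):
            _, F = fr.example_field_1d(tau, 2048)
            k, f = fr.fourier_coeffs_1d(F)
            ft = np.abs(fr.sinc_interpolate(f, k, w))
            sigmas[tau] = fr.fit_gaussian_1d(ft, w).sigma[0]
        assert sigmas[3.0] > sigmas[0.5]


class TestFitGaussian2D:
    @staticmethod
    def model(w1, w2, a, c1, c2, s1, s2):
        return a * np.exp(
            -((w1[:, None] - c1) ** 2) / (2 * s1**2)
            - ((w2[None, :] - c2) ** 2) / (2 * s2**2)
        )

    def test_exact_model_recovered(self):
        w = np.arange(-10, 10, 0.25)
        V = self.model(w, w, 1.5, 0.5, -1.0, 2.0, 4.0)
        fit = fr.fit_gaussian_2d(V, w, w)
        assert fit.sigma[0] == pytest.approx(2.0, abs=1e-6)
        assert fit.sigma[1] == pytest.approx(4.0, abs=1e-6)
        assert fit.center[0] == pytest.approx(0.5, abs=1e-6)

    def test_isotropic_input_gives_equal_sigmas(self):
        w = np.arange(-10, 10, 0.25)
        V = self.model(w, w, 1.0, 0.0, 0.0, 3.0, 3.0)
        fit = fr.fit_gaussian_2d(V, w, w)
        assert abs(fit.sigma[0] - fit.sigma[1]) < 1e-4

    def test_quarter_rotation_swaps_sigmas(self):
        w = np.arange(-10, 10, 0.25)
        V = self.model(w, w, 1.0, 0.0, 0.0, 1.5, 5.0)
        f1 = fr.fit_gaussian_2d(V, w, w)
        f2 = fr.fit_gaussian_2d(np.rot90(V), w, w)
        assert f1.sigma[0] == pytest.approx(f2.sigma[1], abs=1e-6)
        assert f1.sigma[1] == pytest.approx(f2.sigma[0], abs=1e-6)

    def test_noisy_model_sigma_within_two_percent(self):
        rng = np.random.default_rng(5)
        w = np.arange(-10, 10, 0.25)
        V = self.model(w, w, 2.0, 0.0, 0.0, 2.5, 3.5)
        noisy = V + 0.02 * rng.standard_normal(V.shape)  # 1% of a
        fit = fr.fit_gaussian_2d(noisy, w, w)
        assert fit.sigma[0] == pytest.approx(2.5, rel=0.02)
        assert fit.sigma[1] == pytest.approx(3.5, rel=0.02)


class TestDecayFeature:
    def test_invariant_to_cyclic_pixel_shift(self):
        params = fr.TissueParams(tau=1.5, rho=5.0, seed=6, side=128)
        F = fr.make_tissue_image(params, seed_amp=3).image()
        f1 = fr.decay_feature(F).sigma_sum
        f2 = fr.decay_feature(np.roll(F, (17, -9), axis=(0, 1))).sigma_sum
        assert f1 == pytest.approx(f2, abs=1e-6)

    def test_invariant_to_global_phase_offset(self):
        params = fr.TissueParams(tau=1.5, rho=5.0, seed=6, side=128)
        F = fr.make_tissue_image(params, seed_amp=3).image()
        f1 = fr.decay_feature(F).sigma_sum
        f2 = fr.decay_feature(F * np.exp(0.77j)).sigma_sum
        assert f1 == pytest.approx(f2, abs=1e-8)

    def test_pure_amplitude_has_smallest_feature_in_its_category_family(self):
        feats = []
        for tau in (0.0, 1.2, np.pi):
            params = fr.TissueParams(tau=tau, rho=6.0, seed=8, side=128)
            F = fr.make_tissue_image(params, seed_amp=11).image()
            feats.append(fr.decay_feature(F).sigma_sum)
        assert feats[0] == min(feats)

    def test_faster_oscillation_at_full_amplitude_increases_feature(self):
        feats = []
        for rho in (12.0, 6.0, 3.0):  # decreasing correlation length
            params = fr.TissueParams(tau=np.pi, rho=rho, seed=9, side=128)
            F = fr.make_tissue_image(params, seed_amp=13).image()
            feats.append(fr.decay_feature(F).sigma_sum)
        assert feats[0] < feats[1] < feats[2]


class TestUnwrapPhase2D:
    def test_smooth_ramp_recovered_up_to_constant(self):
        x = (np.arange(128) + 0.5) / 128 - 0.5
        ramp = 8.0 * x[:, None] * np.ones((1, 128))
        wrapped = np.angle(np.exp(1j * ramp))
        unwrapped = fr.unwrap_phase_2d(wrapped)
        offset = unwrapped - ramp
        assert np.abs(offset - offset.mean()).max() < 1e-6
        assert abs(offset.mean() / (2 * np.pi) - round(offset.mean() / (2 * np.pi))) < 1e-6

    def test_wrap_free_input_unchanged(self):
        rng = np.random.default_rng(10)
        img = 0.5 * rng.standard_normal((32, 32))
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 4)
        out = fr.unwrap_phase_2d(img)
        assert np.abs(out - img).max() < 1e-10

    def test_output_congruent_mod_2pi(self):
        rng = np.random.default_rng(11)
        from scipy.ndimage import gaussian_filter
        true = 12.0 * gaussian_filter(rng.standard_normal((64, 64)), 8)
        wrapped = np.angle(np.exp(1j * true))
        out = fr.unwrap_phase_2d(wrapped)
        k = (out - wrapped) / (2 * np.pi)
        assert np.abs(k - np.round(k)).max() < 1e-9


def welch_from_scratch(a, b):
    """Independent textbook evaluation of Welch's statistic, df and p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelchTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = fr.welch_t_test(a, a)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_swapping_groups_negates_t_keeps_p(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        r1, r2 = fr.welch_t_test(a, b), fr.welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_hand_worked_example(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        t, df, p = welch_from_scratch(a, b)
        res = fr.welch_t_test(a, b)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_agrees_with_from_scratch_formula_on_random_groups(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.standard_normal(na) * rng.uniform(0.5, 3)
            b = rng.standard_normal(nb) * rng.uniform(0.5, 3) + rng.uniform(-1, 1)
            t, df, p = welch_from_scratch(a, b)
            res = fr.welch_t_test(a, b)
            assert abs(res.t - t) < 1e-10
            assert abs(res.df - df) < 1e-10
            assert abs(res.p - p) < 1e-10

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            fr.welch_t_test([1.0], [1.0, 2.0])


def toy_table():
    rows = []
    rng = np.random.default_rng(13)
    for n in range(12):
        label = "healthy" if n < 6 else "lesion"
        base = 2.0 if n < 6 else 5.0
        for pol in ("h", "v"):
            for i in range(4):
                rows.append({
                    "area": f"a{n}", "subimage": i + 1, "polarization": pol,
                    "sigma1": 1.0, "sigma2": 1.0,
                    "feature": base + rng.normal(0, 0.3), "label": label,
                })
    return fr.feature_table(rows)


class TestGroupAnalysis:
    def test_single_subimage_mean_is_identity(self):
        rows = [
            {"area": "a", "subimage": 1, "polarization": "h", "feature": 3.3,
             "label": "healthy"},
            {"area": "b", "subimage": 1, "polarization": "h", "feature": 4.4,
             "label": "lesion"},
            {"area": "c", "subimage": 1, "polarization": "h", "feature": 3.1,
             "label": "healthy"},
            {"area": "d", "subimage": 1, "polarization": "h", "feature": 4.0,
             "label": "lesion"},
        ]
        per_area, _ = fr.group_analysis(fr.feature_table(rows))
        assert set(per_area["feature"]) == {3.3, 4.4, 3.1, 4.0}

    def test_zscores_have_mean_zero_std_one(self):
        table = toy_table()
        per_area = table.groupby(["area", "polarization"], as_index=False)["feature"].mean()
        for pol in ("h", "v"):
            v = per_area.loc[per_area["polarization"] == pol, "feature"]
            z = (v - v.mean()) / v.std(ddof=1)
            assert abs(z.mean()) < 1e-10
            assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_separated_classes_detected_per_polarization_and_combined(self):
        table = toy_table()
        _, tests = fr.group_analysis(table)
        assert set(tests) == {"h", "v"}
        assert all(r.p < 0.01 for r in tests.values())
        _, combined = fr.group_analysis(table, combine_polarizations=True)
        assert combined["combined"].p < 0.01

    def test_combining_without_both_polarizations_rejected(self):
        table = toy_table()
        only_h = table[table["polarization"] == "h"]
        with pytest.raises(ValueError):
            fr.group_analysis(only_h, combine_polarizations=True)
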