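"""Pretreatment operators: exactness, invariances and the registry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirpowder.core import SpectraSet
from nirpowder.errors import DegenerateInputError, DomainError, ParameterError
from nirpowder.preprocess import (
    ABBREVIATIONS,
    REGISTRY,
    baseline_correct,
    get_pretreatment,
    list_registry,
    msc,
    normalize,
    savgol,
    snv,
    spectro_transform,
    wavelet_denoise,
)


def spectra_from(rows, wn=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    if wn is None:
        wn = np.arange(5000.0, 5000.0 - 8 * rows.shape[1], -8.0)
    return SpectraSet([f"s{i}" for i in range(rows.shape[0])], wn, rows)


class TestSnv:
    def test_hand_example(self):
        out = snv(spectra_from([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        out = snv(spectra_from(rng.random((4, 30))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        s = spectra_from(rng.random((3, 20)))
        np.testing.assert_allclose(snv(snv(s)).absorbance, snv(s).absorbance,
                                   atol=1e-12)

    def test_constant_spectrum_names_sample(self):
        with pytest.raises(DegenerateInputError, match="s1"):
            snv(spectra_from([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


class TestMsc:
    def test_exact_affine_distortion_removed(self):
        ref = np.array([0.1, 0.4, 0.2, 0.6, 0.3])
        x = 0.5 + 2.0 * ref
        out, _ = msc(spectra_from([x]), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)

    def test_identity_when_x_equals_ref(self):
        ref = np.array([0.1, 0.4, 0.2, 0.6, 0.3])
        out, fitted = msc(spectra_from([ref]), reference=ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)
        np.testing.assert_array_equal(fitted, ref)

    def test_hand_normal_equations(self):
        # ref=[1..5], x=[3,5,7,9,11]: a=1, b=2 -> corrected = ref
        out, _ = msc(spectra_from([[3.0, 5.0, 7.0, 9.0, 11.0]]),
                     reference=np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        np.testing.assert_allclose(out.absorbance[0], [1, 2, 3, 4, 5], atol=1e-12)

    def test_default_reference_is_mean_spectrum(self):
        rng = np.random.default_rng(5)
        s = spectra_from(rng.random((4, 12)))
        _, ref = msc(s)
        np.testing.assert_allclose(ref, s.absorbance.mean(axis=0))

    def test_zero_slope_rejected(self):
        ref = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError, match="slope"):
            msc(spectra_from([[2.0, 2.0, 2.0]]), reference=ref)


class TestSavgol:
    def test_first_derivative_of_constant_is_zero(self):
        out = savgol(spectra_from([np.full(30, 3.7)]), 11, 2, deriv=1)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_first_derivative_exact_on_quadratic(self):
        wn = np.arange(5000.0, 4760.0 - 1, -8.0)
        y = (wn / 1000.0) ** 2
        out = savgol(spectra_from([y], wn), 11, 2, deriv=1)
        expected = 2 * wn / 1000.0 ** 2  # d/d(nu) of (nu/1000)^2
        np.testing.assert_allclose(out.absorbance[0], expected, rtol=1e-9)

    def test_smoothing_projects_polynomials_onto_themselves(self):
        wn = np.arange(5000.0, 4760.0 - 1, -8.0)
        y = 1.0 + 0.002 * wn + 3e-7 * wn ** 2
        out = savgol(spectra_from([y], wn), 11, 2, deriv=0)
        np.testing.assert_allclose(out.absorbance[0], y, rtol=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError, match="odd"):
            savgol(spectra_from([np.zeros(30)]), 10, 2)


class TestNormalize:
    def test_hand_vector_example(self):
        out = normalize(spectra_from([[3.0, 4.0]]))
        np.testing.assert_allclose(out.absorbance[0], [0.6, 0.8])

    def test_unit_norm_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.random((3, 15))
        out1 = normalize(spectra_from(a))
        out7 = normalize(spectra_from(7.0 * a))
        np.testing.assert_allclose(np.linalg.norm(out1.absorbance, axis=1), 1.0)
        np.testing.assert_allclose(out1.absorbance, out7.absorbance, atol=1e-12)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize(spectra_from([[0.0, 0.0, 0.0]]))


class TestBaseline:
    def test_straight_line_removed(self):
        wn = np.arange(5000.0, 4800.0, -8.0)
        out = baseline_correct(spectra_from([0.2 + 0.001 * wn], wn), order=1)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_invariant_to_added_linear_trend(self):
        rng = np.random.default_rng(7)
        wn = np.arange(5000.0, 4800.0, -8.0)
        y = rng.random(wn.size)
        a = baseline_correct(spectra_from([y], wn), order=1).absorbance
        b = baseline_correct(spectra_from([y + 3.0 + 0.002 * wn], wn), order=1).absorbance
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_order_zero_is_mean_subtraction(self):
        rng = np.random.default_rng(8)
        y = rng.random(25)
        out = baseline_correct(spectra_from([y]), order=0)
        np.testing.assert_allclose(out.absorbance[0], y - y.mean(), atol=1e-12)

    def test_order_bound(self):
        with pytest.raises(ParameterError):
            baseline_correct(spectra_from([[1.0, 2.0]]), order=5)


class TestSpectroTransform:
    def test_perfect_reflector(self):
        out = spectro_transform(spectra_from([[0.0, 0.0]]), mode="kubelka_munk")
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_hand_value(self):
        # A = log10(4) -> R = 0.25 -> f(R) = 0.75^2 / 0.5 = 1.125
        out = spectro_transform(spectra_from([[np.log10(4.0), np.log10(4.0)]]))
        np.testing.assert_allclose(out.absorbance, 1.125, rtol=1e-12)

    def test_strictly_increasing_in_absorbance(self):
        a = np.linspace(0.01, 2.0, 50)
        out = spectro_transform(spectra_from([a]))
        assert np.all(np.diff(out.absorbance[0]) > 0)

    def test_reflectance_mode(self):
        out = spectro_transform(spectra_from([[1.0, 2.0]]), mode="to_reflectance")
        np.testing.assert_allclose(out.absorbance[0], [0.1, 0.01])

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DomainError):
            spectro_transform(spectra_from([[-0.5, 0.2]]))


class TestWaveletDenoise:
    def test_zero_spectrum_maps_to_zero(self):
        out = wavelet_denoise(spectra_from([np.zeros(128)]))
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(9)
        y = rng.random(128)
        out = wavelet_denoise(spectra_from([y]), threshold=0.0)
        np.testing.assert_allclose(out.absorbance[0], y, atol=1e-10)

    def test_denoising_reduces_rmse_to_clean_truth(self):
        wn = np.arange(6000.0, 6000.0 - 8 * 256, -8.0)
        clean = np.exp(-0.5 * ((wn - 5000.0) / 120.0) ** 2)
        improved = 0
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            noisy = clean + 0.05 * rng.standard_normal(wn.size)
            out = wavelet_denoise(spectra_from([noisy], wn)).absorbance[0]
            if np.sqrt(np.mean((out - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2)):
                improved += 1
        assert improved >= 95

    def test_invalid_settings_rejected(self):
        with pytest.raises(ParameterError):
            wavelet_denoise(spectra_from([np.zeros(64)]), wavelet="nosuch")
        with pytest.raises(ParameterError):
            wavelet_denoise(spectra_from([np.zeros(64)]), level=99)


class TestRegistry:
    def test_registry_has_the_ten_screened_methods(self):
        assert len(list_registry()) == 10
        assert set(ABBREVIATIONS) == set(REGISTRY)

    def test_raw_is_identity(self, small_spectra):
        out = get_pretreatment("raw").fit_transform(small_spectra)
        np.testing.assert_array_equal(out.absorbance, small_spectra.absorbance)

    def test_unknown_name_lists_options(self):
        with pytest.raises(LookupError, match="snv"):
            get_pretreatment("savgol3")

    def test_abbreviation_lookup(self):
        assert get_pretreatment("WDS").name == "wavelet_denoise"
        assert get_pretreatment("S-G 1st").name == "sg_1st"

    @settings(deadline=None, max_examples=20)
    @given(name=st.sampled_from(REGISTRY), seed=st.integers(0, 10_000))
    def test_shape_and_order_preserved(self, name, seed):
        rng = np.random.default_rng(seed)
        wn = np.arange(6000.0, 6000.0 - 8 * 128, -8.0)
        s = SpectraSet(["a", "b", "c"], wn, 0.2 + rng.random((3, 128)))
        p = get_pretreatment(name).fit(s)
        out = p.transform(s)
        assert out.absorbance.shape == s.absorbance.shape
        assert out.sample_ids == s.sample_ids

    def test_msc_state_learned_once_and_reused(self, small_spectra):
        p = get_pretreatment("msc").fit(small_spectra)
        ref = p.fitted_state["reference"].copy()
        other = small_spectra.with_absorbance(small_spectra.absorbance * 1.5)
        p.transform(other)
        p.fit(other)  # no-op: state already learned
        np.testing.assert_array_equal(p.fitted_state["reference"], ref)

    def test_msc_transform_requires_fit(self, small_spectra):
        with pytest.raises(DegenerateInputError, match="fitted"):
            get_pretreatment("msc").transform(small_spectra)
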