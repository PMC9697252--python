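"""Feature-image filters against closed forms and brute-force oracles."""

import numpy as np
import pytest

import mpfusion as mp
from mpfusion.filters import (FilterSpec, apply_filter, gabor_imag, gabor_real)
from mpfusion.voi import PerspectiveStack

from conftest import bf_bilateral, bf_gabor, bf_log

RNG = np.random.default_rng(2024)


def random_image(n, scale=1.0):
    return RNG.random((n, n)) * scale


class TestLogKernel:
    def test_closed_form_at_origin(self):
        k = mp.log_kernel(1.0)
        r = k.shape[0] // 2
        assert k[r, r] == pytest.approx(-1.0 / np.pi, abs=1e-12)

    def test_zero_on_inflection_circle(self):
        # the bracket vanishes where x^2 + y^2 = 2 sigma^2
        k = mp.log_kernel(1.0)
        r = k.shape[0] // 2
        assert k[r + 1, r + 1] == pytest.approx(0.0, abs=1e-12)

    def test_radial_symmetry(self):
        k = mp.log_kernel(1.7)
        np.testing.assert_allclose(k, k[::-1, ::-1], atol=1e-15)
        np.testing.assert_allclose(k, k.T, atol=1e-15)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            mp.log_kernel(2.0, radius=3)  # < ceil(3 sigma)


class TestGaborKernel:
    def test_real_part_at_origin(self):
        spec = FilterSpec(family="gabor", sigma_x=2.0, sigma_y=3.0)
        k = gabor_real(spec)
        r = k.shape[0] // 2
        assert k[r, r] == pytest.approx(1.0 / (2 * np.pi * 2.0 * 3.0), abs=1e-12)

    def test_imag_part_at_origin_is_zero(self):
        k = gabor_imag(FilterSpec(family="gabor"))
        r = k.shape[0] // 2
        assert k[r, r] == pytest.approx(0.0, abs=1e-15)

    def test_zero_frequency_reduces_to_gaussian(self):
        spec = FilterSpec(family="gabor", sigma_x=2.0, sigma_y=2.0,
                          omega_x0=0.0, omega_y0=0.0)
        k = mp.gabor_kernel(spec)
        ax = np.arange(-k.shape[0] // 2 + 1, k.shape[0] // 2 + 1)
        x, y = np.meshgrid(ax, ax, indexing="ij")
        gauss = np.exp(-0.5 * (x**2 + y**2) / 4.0) / (2 * np.pi * 4.0)
        np.testing.assert_allclose(k.real, gauss, atol=1e-15)
        np.testing.assert_allclose(k.imag, 0.0, atol=1e-15)


@pytest.mark.parametrize("n", [7, 9])
class TestBruteForceOracles:
    """Every filter matches its nested-loop direct-sum oracle to 1e-10."""

    def test_log(self, n):
        spec = FilterSpec(family="log", sigma=1.5)
        img = random_image(n)
        np.testing.assert_allclose(mp.apply_log(img, spec).data,
                                   bf_log(img, spec), atol=1e-10)

    def test_gabor(self, n):
        spec = FilterSpec(family="gabor")
        img = random_image(n)
        np.testing.assert_allclose(mp.apply_gabor(img, spec).data,
                                   bf_gabor(img, spec), atol=1e-10)

    def test_bilateral(self, n):
        spec = FilterSpec(family="bilateral", window_N=5, sigma_S=1.5, sigma_R=0.2)
        img = random_image(n)
        np.testing.assert_allclose(mp.bilateral_filter(img, spec).data,
                                   bf_bilateral(img, spec), atol=1e-10)

    def test_trilateral(self, n):
        spec = FilterSpec(family="trilateral", window_N=5,
                          sigma_S=1.5, sigma_R=0.2, sigma_L=0.3)
        img = random_image(n)
        np.testing.assert_allclose(
            mp.trilateral_filter(img, spec).data,
            bf_bilateral(img, spec, laplacian_term=True), atol=1e-10)


def test_log_equals_smooth_then_laplacian():
    """Derivative-of-convolution identity: convolving with the closed-form
    LoG kernel approximates Gaussian smoothing followed by the discrete
    Laplacian (agreement improves with sigma; checked at sigma=2)."""
    from scipy.ndimage import convolve, gaussian_filter
    from mpfusion.filters import LAPLACIAN_STENCIL
    img = np.random.default_rng(3).random((32, 32))
    spec = FilterSpec(family="log", sigma=2.0)
    direct = mp.apply_log(img, spec).data
    two_step = convolve(gaussian_filter(img, 2.0, mode="mirror"),
                        LAPLACIAN_STENCIL, mode="mirror")
    span = direct.max() - direct.min()
    # the discrete 4-neighbour Laplacian carries a small amplitude bias
    assert np.abs(direct - two_step).max() < 0.10 * span
    assert np.corrcoef(direct.ravel(), two_step.ravel())[0, 1] > 0.99


class TestConstantImageIdentities:
    CONST = np.full((16, 16), 0.42)

    def test_log_response_is_near_zero(self):
        # the truncated discrete kernel integrates to ~0, not exactly 0
        out = mp.apply_log(self.CONST, FilterSpec(family="log", sigma=2.0)).data
        np.testing.assert_allclose(out, 0.0, atol=5e-3)

    def test_bilateral_identity(self):
        out = mp.bilateral_filter(self.CONST, FilterSpec(family="bilateral")).data
        np.testing.assert_allclose(out, self.CONST, atol=1e-12)

    def test_trilateral_identity(self):
        out = mp.trilateral_filter(self.CONST, FilterSpec(family="trilateral")).data
        np.testing.assert_allclose(out, self.CONST, atol=1e-12)

    def test_difference_of_trilateral_is_zero(self):
        out = mp.difference_of_trilateral(
            self.CONST, FilterSpec(family="diff_trilateral")).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestLimitReductions:
    def test_trilateral_to_bilateral_as_sigma_l_grows(self):
        img = random_image(12)
        tri = FilterSpec(family="trilateral", sigma_L=1e9)
        bil = FilterSpec(family="bilateral")
        np.testing.assert_allclose(mp.trilateral_filter(img, tri).data,
                                   mp.bilateral_filter(img, bil).data, atol=1e-6)

    def test_bilateral_to_gaussian_as_sigma_r_grows(self):
        img = random_image(12)
        spec = FilterSpec(family="bilateral", sigma_R=1e9)
        # oracle: spatial-only normalised window mean
        half = spec.window_N // 2
        padded = np.pad(img, half, mode="reflect")
        expected = np.zeros_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                num = den = 0.0
                for dx in range(-half, half + 1):
                    for dy in range(-half, half + 1):
                        w = np.exp(-(dx**2 + dy**2) / (2 * spec.sigma_S**2))
                        num += w * padded[i + dx + half, j + dy + half]
                        den += w
                expected[i, j] = num / den
        np.testing.assert_allclose(mp.bilateral_filter(img, spec).data,
                                   expected, atol=1e-6)

    def test_gabor_to_gaussian_as_frequency_vanishes(self):
        img = random_image(12)
        zero = FilterSpec(family="gabor", omega_x0=0.0, omega_y0=0.0)
        out = mp.apply_gabor(img, zero).data
        from scipy.ndimage import convolve
        gauss = gabor_real(zero)
        np.testing.assert_allclose(out, convolve(img, gauss, mode="mirror"),
                                   atol=1e-12)


class TestWindowedMeanProperties:
    def test_convex_combination_bounds(self):
        # output lies within the local window's min/max
        img = random_image(14)
        for family in ("bilateral", "trilateral"):
            spec = FilterSpec(family=family, window_N=5)
            out = apply_filter(img, spec).data
            half = spec.window_N // 2
            padded = np.pad(img, half, mode="reflect")
            for i in range(img.shape[0]):
                for j in range(img.shape[1]):
                    win = padded[i:i + 2 * half + 1, j:j + 2 * half + 1]
                    assert win.min() - 1e-12 <= out[i, j] <= win.max() + 1e-12

    def test_shape_and_finiteness(self):
        img = random_image(11)
        for family in ("log", "gabor", "bilateral", "trilateral", "diff_trilateral"):
            out = apply_filter(img, FilterSpec(family=family)).data
            assert out.shape == img.shape
            assert np.all(np.isfinite(out))

    def test_nonfinite_input_rejected(self):
        img = random_image(8)
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            mp.bilateral_filter(img, FilterSpec(family="bilateral"))


class TestDifferenceOfTrilateral:
    def test_equals_two_independent_calls(self):
        img = random_image(10)
        spec = FilterSpec(family="diff_trilateral", sigma_S=1.5, k=2.0)
        from dataclasses import replace
        wide = replace(spec, family="trilateral", sigma_S=spec.k * spec.sigma_S)
        narrow = replace(spec, family="trilateral")
        expected = (mp.trilateral_filter(img, wide).data
                    - mp.trilateral_filter(img, narrow).data)
        np.testing.assert_allclose(mp.difference_of_trilateral(img, spec).data,
                                   expected, atol=1e-12)

    def test_k_must_exceed_one(self):
        with pytest.raises(ValueError):
            mp.difference_of_trilateral(random_image(8),
                                        FilterSpec(family="diff_trilateral", k=1.0))


class TestFilterStack:
    def _stack(self, const=None):
        slices = [np.full((56, 56), 0.3) if const is None else const
                  for _ in range(6)]
        return PerspectiveStack("V1", slices, list(range(6)))

    def test_six_in_six_out_order_preserved(self):
        slices = [np.full((56, 56), i / 10) for i in range(6)]
        stack = PerspectiveStack("V1", slices, [0, 11, 22, 33, 44, 55])
        out = mp.filter_stack(stack, FilterSpec(family="bilateral"))
        assert len(out.slices) == 6
        assert out.slice_indices == [0, 11, 22, 33, 44, 55]
        for i, s in enumerate(out.slices):
            np.testing.assert_allclose(s, i / 10, atol=1e-12)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(family="median")
        with pytest.raises(ValueError):
            FilterSpec(family="bilateral", window_N=4)
        with pytest.raises(ValueError):
            FilterSpec(family="log", sigma=-1.0)
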