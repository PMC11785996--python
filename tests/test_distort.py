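import numpy as np
import pytest

from simqual import distort
from simqual.distort import (
    DEFAULT_SCHEDULE,
    DISTORTIONS,
    DistortionSpec,
    ParameterSchedule,
    apply,
    bias_field,
    bias_polynomial,
    elastic_deform,
    elastic_field,
    gamma_transform,
    gaussian_blur,
    gaussian_noise,
    ghosting,
    intensity_shift,
    replace_reflect,
    stripes,
    translate,
)


class TestTranslate:
    def test_zero_is_identity(self, phantom_image):
        assert np.array_equal(translate(phantom_image, 0, 0), phantom_image)

    def test_integer_shift_moves_impulse(self):
        img = np.zeros((16, 16))
        img[8, 5] = 1.0
        out = translate(img, fx=3 / 16, fy=0)
        assert out[8, 8] == pytest.approx(1.0)
        assert out[8, 5] == pytest.approx(0.0)

    def test_strength1_is_one_percent(self):
        params = ParameterSchedule().resolve("translation", 1)
        assert params == {"fx": 0.01, "fy": 0.01}

    def test_rejects_half_image_shift(self, phantom_image):
        with pytest.raises(ValueError):
            translate(phantom_image, 0.6, 0)


class TestElastic:
    def test_sigma_zero_identity(self, phantom_image):
        out = elastic_deform(phantom_image, grid_n=5, sigma=0.0, seed=3)
        assert np.array_equal(out, phantom_image)

    def test_seed_determinism(self, phantom_image):
        a = elastic_deform(phantom_image, 5, 2.0, seed=11)
        b = elastic_deform(phantom_image, 5, 2.0, seed=11)
        assert np.array_equal(a, b)
        c = elastic_deform(phantom_image, 5, 2.0, seed=12)
        assert not np.array_equal(a, c)

    def test_dense_field_matches_bilinear_oracle(self):
        grid_n, sigma, seed, shape = 4, 3.0, 7, (33, 65)
        field = elastic_field(shape, grid_n, sigma, seed)
        control = np.random.default_rng(seed).normal(0, sigma, size=(2, grid_n, grid_n))
        h, w = shape
        probes = [(0, 0), (h - 1, w - 1), (16, 32), (5, 50), (20, 7)]
        for r, c in probes:
            gr = r * (grid_n - 1) / (h - 1)
            gc = c * (grid_n - 1) / (w - 1)
            r0, c0 = int(np.floor(gr)), int(np.floor(gc))
            r1, c1 = min(r0 + 1, grid_n - 1), min(c0 + 1, grid_n - 1)
            fr, fc = gr - r0, gc - c0
            for axis in range(2):
                g = control[axis]
                expected = (
                    g[r0, c0] * (1 - fr) * (1 - fc)
                    + g[r1, c0] * fr * (1 - fc)
                    + g[r0, c1] * (1 - fr) * fc
                    + g[r1, c1] * fr * fc
                )
                assert field[axis, r, c] == pytest.approx(expected, abs=1e-9)


class TestGamma:
    def test_identity(self, phantom_image):
        assert np.allclose(gamma_transform(phantom_image, 1.0), phantom_image)

    def test_midpoint_squared(self):
        img = np.zeros((8, 8))
        img[0, 0], img[0, 1] = 10.0, 5.0  # min 0, max 10, mid 5
        out = gamma_transform(img, 2.0)
        assert out[0, 1] == pytest.approx(0.25 * 10.0)

    @pytest.mark.parametrize("gamma", [0.3, 0.7, 1.8, 3.0])
    def test_range_exactly_preserved(self, phantom_image, gamma):
        out = gamma_transform(phantom_image, gamma)
        assert out.min() == pytest.approx(phantom_image.min(), abs=1e-9)
        assert out.max() == pytest.approx(phantom_image.max(), abs=1e-9)


class TestIntensityShift:
    def test_shift_by_fraction_of_range(self):
        img = np.zeros((8, 8))
        img[4, 4] = 10.0
        out = intensity_shift(img, 0.1)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[4, 4] == pytest.approx(11.0)

    def test_zero_identity(self, phantom_image):
        assert np.allclose(intensity_shift(phantom_image, 0.0), phantom_image)


class TestGhosting:
    def test_zero_amplitude_identity(self, phantom_image):
        out = ghosting(phantom_image, 4, 0.0)
        assert np.abs(out - phantom_image).max() < 1e-9

    def test_output_real_residue_small(self, phantom_image):
        out = ghosting(phantom_image, 4, 0.3)
        spectrum = np.fft.fft2(phantom_image)
        # direct complex reconstruction to measure the imaginary residue
        n = phantom_image.shape[0]
        idx = np.arange(n)
        lines = (idx % 4 == 0) & (idx != 0)
        lines = lines | lines[(n - idx) % n]
        factor = np.ones(n)
        factor[lines] = 0.7
        complex_out = np.fft.ifft2(spectrum * factor[:, None])
        L = phantom_image.max() - phantom_image.min()
        assert np.abs(complex_out.imag).max() <= 1e-9 * L
        assert np.allclose(out, complex_out.real)

    def test_parseval_energy_bookkeeping(self, phantom_image):
        amp = 0.4
        out = ghosting(phantom_image, 4, amp)
        spectrum = np.fft.fft2(phantom_image)
        n = phantom_image.shape[0]
        idx = np.arange(n)
        lines = (idx % 4 == 0) & (idx != 0)
        lines = lines | lines[(n - idx) % n]
        removed = (1 - (1 - amp) ** 2) * np.sum(np.abs(spectrum[lines, :]) ** 2)
        energy_in = np.sum(phantom_image**2)
        energy_out = np.sum(out**2)
        expected_loss = removed / phantom_image.size
        assert energy_in - energy_out == pytest.approx(expected_loss, rel=1e-9)


class TestStripes:
    def test_amplitude_one_identity(self, phantom_image):
        out = stripes(phantom_image, amplitude=1.0)
        assert np.abs(out - phantom_image).max() < 1e-9

    def test_pure_sinusoid_doubles(self):
        h, w, u, v = 32, 32, 4, 6
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        img = np.cos(2 * np.pi * (u * rr / h + v * cc / w))
        out = stripes(img, (u, v), amplitude=2.0)
        assert np.allclose(out, 2 * img, atol=1e-9)

    def test_real_output(self, phantom_image):
        out = stripes(phantom_image, amplitude=50.0)
        L = phantom_image.max() - phantom_image.min()
        # real part of a conjugate-symmetric spectrum: residue is bounded
        spectrum = np.fft.fft2(phantom_image)
        h, w = phantom_image.shape
        u, v = h // 8, w // 6
        spectrum[u, v] *= 50.0
        spectrum[(h - u) % h, (w - v) % w] *= 50.0
        assert np.abs(np.fft.ifft2(spectrum).imag).max() <= 1e-9 * L

    def test_dc_rejected(self, phantom_image):
        with pytest.raises(ValueError):
            stripes(phantom_image, (0, 0), 2.0)


class TestBiasField:
    def test_zero_coeffs_identity(self, phantom_image):
        out = bias_field(phantom_image, coeffs=np.zeros(10), scale=1.0)
        assert np.allclose(out, phantom_image)

    def test_constant_polynomial(self, phantom_image):
        coeffs = np.zeros(10)
        coeffs[0] = 0.7  # constant term
        out = bias_field(phantom_image, coeffs=coeffs, scale=1.0)
        assert np.allclose(out, phantom_image * np.exp(0.7))

    def test_field_matches_monomial_oracle(self):
        rng = np.random.default_rng(5)
        coeffs = rng.uniform(-1, 1, 10)
        shape = (21, 31)
        poly = bias_polynomial(shape, coeffs)
        exponents = [(i, j) for i in range(4) for j in range(4) if i + j <= 3]
        for r, c in [(0, 0), (10, 15), (20, 30), (5, 25)]:
            x = -1 + 2 * c / (shape[1] - 1)
            y = -1 + 2 * r / (shape[0] - 1)
            expected = sum(k * x**i * y**j for k, (i, j) in zip(coeffs, exponents))
            assert poly[r, c] == pytest.approx(expected, abs=1e-12)


class TestGaussianNoise:
    def test_zero_sigma_identity(self, phantom_image):
        assert np.array_equal(gaussian_noise(phantom_image, 0.0, 1), phantom_image)

    def test_noise_std_calibrated(self, phantom_image):
        sigma_frac = 0.02
        L = phantom_image.max() - phantom_image.min()
        out = gaussian_noise(phantom_image, sigma_frac, seed=9)
        measured = (out - phantom_image).std()
        assert measured == pytest.approx(sigma_frac * L, rel=0.05)

    def test_seed_determinism(self, phantom_image):
        a = gaussian_noise(phantom_image, 0.01, seed=4)
        b = gaussian_noise(phantom_image, 0.01, seed=4)
        assert np.array_equal(a, b)


class TestGaussianBlur:
    def test_zero_sigma_identity(self, phantom_image):
        assert np.array_equal(gaussian_blur(phantom_image, 0.0), phantom_image)

    def test_constant_unchanged(self):
        img = np.full((16, 16), 3.0)
        assert np.allclose(gaussian_blur(img, 2.0), img)

    def test_impulse_response_matches_kernel(self):
        sigma = 1.2
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_blur(img, sigma)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        sl = slice(16 - radius, 16 + radius + 1)
        assert np.abs(out[sl, sl] - kernel).max() < 1e-6

    def test_mean_preserved(self, phantom_image):
        out = gaussian_blur(phantom_image, 2.0)
        assert out.mean() == pytest.approx(phantom_image.mean(), rel=0.005)


class TestReplaceReflect:
    def test_zero_fraction_identity(self, phantom_image):
        assert np.array_equal(replace_reflect(phantom_image, 0.0), phantom_image)

    def test_symmetric_input_invariant(self):
        half = np.random.default_rng(3).random((16, 8))
        img = np.hstack([half, half[:, ::-1]])
        for frac in (0.3, 1.0):
            assert np.array_equal(replace_reflect(img, frac, "left"), img)

    def test_impulse_duplicated_via_mirror(self):
        w = 16
        img = np.zeros((8, w))
        k = 3
        img[4, w // 2 + k] = 1.0
        out = replace_reflect(img, 1.0, side="left")
        assert out[4, w // 2 - 1 - k] == 1.0
        assert out[4, w // 2 + k] == 1.0  # source side untouched


class TestScheduleAndDispatch:
    def test_all_magnitudes_strictly_monotone(self):
        sched = ParameterSchedule()
        for name in DEFAULT_SCHEDULE:
            mags = sched.magnitudes(name)
            assert np.all(np.diff(mags) > 0), name

    def test_gamma_low_strictly_decreasing_below_one(self):
        gammas = [DEFAULT_SCHEDULE["gamma_low"][s]["gamma"] for s in range(1, 6)]
        assert all(g < 1 for g in gammas)
        assert np.all(np.diff(gammas) < 0)

    def test_elastic_grid_count_decreases(self):
        grids = [DEFAULT_SCHEDULE["elastic"][s]["grid_n"] for s in range(1, 6)]
        assert np.all(np.diff(grids) < 0)

    def test_override_merging(self):
        sched = ParameterSchedule({"gaussian_noise": {1: {"sigma_frac": 0.42}}})
        assert sched.resolve("gaussian_noise", 1)["sigma_frac"] == 0.42
        assert sched.resolve("gaussian_noise", 2) == DEFAULT_SCHEDULE["gaussian_noise"][2]

    def test_apply_deterministic(self, phantom_image):
        spec = DistortionSpec("gaussian_noise", 3, seed=7)
        a = apply(spec, phantom_image)
        b = apply(spec, phantom_image)
        assert np.array_equal(a, b)

    def test_unknown_name_rejected(self, phantom_image):
        with pytest.raises(ValueError):
            apply(DistortionSpec("motion", 1), phantom_image)

    @pytest.mark.parametrize("name", sorted(DISTORTIONS))
    def test_shape_preserved_at_all_strengths(self, name, phantom_image):
        small = phantom_image[::4, ::4]  # 60×60 keeps this quick
        for strength in range(1, 6):
            out = apply(DistortionSpec(name, strength, seed=1), small)
            assert out.shape == small.shape
            assert np.all(np.isfinite(out))
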