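"""Red-leak correction and translation registration."""

import numpy as np
import pytest
from scipy import ndimage

import ndvicam as nc
from ndvicam.errors import DegenerateSignalError, DimensionError, NoFeaturesError
from ndvicam.spectral import STANDARD_GRID


def refl(values, mask=None, band=None):
    return nc.ReflectanceImage(np.asarray(values, float), band or nc.NIR_750, mask)


def smooth_field(seed=7, shape=(96, 96)):
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(50.0, 20.0, shape), 2.0)
    return np.clip(field, 0.0, 100.0)


class TestEstimateLeakFraction:
    red_band = nc.BandDefinition("red", 620.0, 60.0)
    nir_band = nc.BandDefinition("nir", 750.0, 60.0)

    @staticmethod
    def box_transmission(red_band, red_t, nir_band, nir_t):
        t = np.zeros_like(STANDARD_GRID)
        t[(STANDARD_GRID >= red_band.lo) & (STANDARD_GRID <= red_band.hi)] = red_t
        t[(STANDARD_GRID >= nir_band.lo) & (STANDARD_GRID <= nir_band.hi)] = nir_t
        return nc.SpectralCurve(STANDARD_GRID, t, "box")

    def test_opaque_red_band_means_no_leak(self):
        curve = self.box_transmission(self.red_band, 0.0, self.nir_band, 0.85)
        leak = nc.estimate_leak_fraction(curve, self.red_band, self.nir_band)
        assert leak.fraction == 0.0

    def test_flat_curves_give_closed_form_ratio(self):
        # equal band widths, flat transmission: f = 0.10 / (0.10 + 0.85)
        curve = self.box_transmission(self.red_band, 0.10, self.nir_band, 0.85)
        leak = nc.estimate_leak_fraction(curve, self.red_band, self.nir_band)
        assert leak.fraction == pytest.approx(0.10 / 0.95, abs=1e-9)

    @pytest.mark.parametrize("red_t", [0.05, 0.10, 0.15])
    def test_any_red_transmission_in_filter_range_leaks(self, red_t):
        curve = self.box_transmission(self.red_band, red_t, self.nir_band, 0.85)
        leak = nc.estimate_leak_fraction(curve, self.red_band, self.nir_band)
        assert leak.fraction > 0.0

    def test_zero_signal_is_degenerate(self):
        curve = nc.SpectralCurve.flat(0.0)
        with pytest.raises(DegenerateSignalError):
            nc.estimate_leak_fraction(curve, self.red_band, self.nir_band)


class TestCorrectNirLeak:
    def test_arithmetic_example(self):
        out = nc.correct_nir_leak(
            refl([[50.0]]), refl([[20.0]], band=nc.RED_620), nc.LeakModel(0.10)
        )
        assert out.values[0, 0] == pytest.approx(48.0)

    def test_forward_contaminate_then_invert(self):
        nir_true, red, f = 5.0, 20.0, 0.10
        contaminated = refl([[nir_true + f * red]])
        out = nc.correct_nir_leak(contaminated, refl([[red]], band=nc.RED_620),
                                  nc.LeakModel(f))
        assert out.values[0, 0] == pytest.approx(nir_true, abs=1e-12)
        raw_ndvi = nc.ndvi_value(nir_true + f * red, red)
        true_ndvi = nc.ndvi_value(nir_true, red)
        assert raw_ndvi == pytest.approx(-0.481, abs=5e-4)
        assert true_ndvi == pytest.approx(-0.600, abs=1e-12)

    def test_zero_fraction_is_exact_identity(self):
        vals = smooth_field(1, (10, 10))
        out = nc.correct_nir_leak(refl(vals), refl(vals, band=nc.RED_620), nc.LeakModel(0.0))
        np.testing.assert_array_equal(out.values, vals)

    def test_round_trip_over_fraction_range(self):
        rng = np.random.default_rng(5)
        nir_true = rng.uniform(0, 80, (20, 20))
        red = rng.uniform(0, 90, (20, 20))
        for f in np.linspace(0.0, 0.2, 9):
            contaminated = refl(nir_true + f * red)
            out = nc.correct_nir_leak(contaminated, refl(red, band=nc.RED_620),
                                      nc.LeakModel(f))
            np.testing.assert_allclose(out.values, nir_true, atol=1e-10)

    def test_negative_result_clamped_and_flagged(self):
        out = nc.correct_nir_leak(refl([[1.0]]), refl([[50.0]], band=nc.RED_620),
                                  nc.LeakModel(0.10))
        assert out.values[0, 0] == 0.0
        assert not out.mask[0, 0]

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            nc.correct_nir_leak(refl(np.zeros((2, 2))), refl(np.zeros((3, 3))),
                                nc.LeakModel(0.1))

    def test_uncorrected_leak_biases_ndvi_upward(self):
        """Red leaking onto the NIR channel inflates NDVI wherever red > 0."""
        rng = np.random.default_rng(9)
        nir_true = rng.uniform(5, 60, 50)
        red = rng.uniform(1, 60, 50)
        f = 0.12
        for n, r in zip(nir_true, red):
            assert nc.ndvi_value(n + f * r, r) > nc.ndvi_value(n, r)


class TestEstimateShift:
    def test_self_alignment(self):
        img = refl(smooth_field())
        s = nc.estimate_shift(img, img, 8)
        assert (s.dx, s.dy) == (0.0, 0.0)
        assert s.score == pytest.approx(1.0)

    def test_known_synthetic_shift(self):
        img = refl(smooth_field())
        shifted = nc.apply_shift(img, nc.RigidShift(5.0, -3.0))
        s = nc.estimate_shift(img, shifted, 8)
        assert abs(s.dx - 5.0) <= 0.5 and abs(s.dy - (-3.0)) <= 0.5

    def test_recovery_over_seeded_random_shifts(self):
        """50 random integer shifts within ±20 px recovered to <= 0.5 px."""
        img = refl(smooth_field())
        for k in range(50):
            rng = np.random.default_rng(100 + k)
            dx, dy = (int(v) for v in rng.integers(-20, 21, 2))
            shifted = nc.apply_shift(img, nc.RigidShift(float(dx), float(dy)))
            s = nc.estimate_shift(img, shifted, 24)
            assert abs(s.dx - dx) <= 0.5 and abs(s.dy - dy) <= 0.5

    def test_recovery_with_noise_at_20db(self):
        base = smooth_field(3)
        rng = np.random.default_rng(17)
        noise_sd = base.std() / 10.0  # 20 dB signal-to-noise
        img = refl(base)
        shifted = nc.apply_shift(img, nc.RigidShift(4.0, 6.0))
        noisy = refl(np.clip(shifted.values + rng.normal(0, noise_sd, base.shape), 0, 100),
                     mask=shifted.mask)
        s = nc.estimate_shift(img, noisy, 10)
        assert abs(s.dx - 4.0) <= 0.5 and abs(s.dy - 6.0) <= 0.5

    def test_flat_image_has_no_features(self):
        flat = refl(np.full((64, 64), 30.0))
        with pytest.raises(NoFeaturesError):
            nc.estimate_shift(flat, flat, 8)


class TestApplyShift:
    def test_zero_shift_is_identity(self):
        img = refl(smooth_field(2))
        out = nc.apply_shift(img, nc.RigidShift(0.0, 0.0))
        np.testing.assert_array_equal(out.values, img.values)

    def test_integer_shift_round_trip_on_interior(self):
        img = refl(smooth_field(4))
        s = nc.RigidShift(3.0, -2.0)
        back = nc.apply_shift(nc.apply_shift(img, s), s.negated())
        interior = back.mask
        assert interior.sum() > 0
        np.testing.assert_allclose(back.values[interior], img.values[interior], atol=1e-6)

    def test_fractional_shift_exact_on_linear_ramp(self):
        # bilinear interpolation reproduces affine images exactly
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        img = refl(0.5 * xx + 0.25 * yy + 3.0)
        out = nc.apply_shift(img, nc.RigidShift(1.5, 0.5))
        yy_s, xx_s = yy - 0.5, xx - 1.5
        expected = 0.5 * xx_s + 0.25 * yy_s + 3.0
        np.testing.assert_allclose(out.values[out.mask], expected[out.mask], atol=1e-9)

    def test_out_of_frame_columns_masked(self):
        img = refl(smooth_field(6, (16, 16)))
        out = nc.apply_shift(img, nc.RigidShift(3.0, 0.0))
        assert not out.mask[:, :3].any()
        assert out.mask[:, 3:].all()
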