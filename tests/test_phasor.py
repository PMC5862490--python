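import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimphasor import (
    AcquisitionMeta,
    DecayHistogram,
    GaussianIRF,
    LifetimeMixture,
    PixelMask,
    TCSPCImage,
    aggregate_measurement,
    apply_calibration,
    apply_tac_truncation,
    calibrate,
    generate_decay,
    mixture_phasor,
    phasor_image,
    pixel_phasor,
    single_exp_phasor,
    universal_circle,
)
from flimphasor.phasor import CalibrationTransform, PhasorImage


def _circle_residual(g, s):
    return (g - 0.5) ** 2 + s**2 - 0.25


class TestSingleExpPhasor:
    def test_algebraic_midpoint(self):
        # omega*tau = 1 sits at the apex of the semicircle
        assert single_exp_phasor(1.0, 1.0) == pytest.approx((0.5, 0.5))

    def test_limits(self):
        assert single_exp_phasor(0.0, 2.0) == (1.0, 0.0)
        g, s = single_exp_phasor(1e9, 2.0)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-8)

    def test_lies_on_universal_circle_for_all_tau(self):
        omega = AcquisitionMeta().omega(1)
        g, s = single_exp_phasor(np.geomspace(1e-3, 1e3, 50), omega)
        np.testing.assert_allclose(_circle_residual(g, s), 0.0, atol=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            single_exp_phasor(-1.0, 1.0)


class TestMixturePhasor:
    def test_single_component_degenerates(self):
        omega = 0.7
        mix = LifetimeMixture((2.0,), (1.0,))
        assert mixture_phasor(mix, omega) == pytest.approx(single_exp_phasor(2.0, omega))

    def test_equal_lifetimes_collapse(self):
        omega = 0.7
        mix = LifetimeMixture((2.0, 2.0), (0.5, 0.5))
        assert mixture_phasor(mix, omega) == pytest.approx(single_exp_phasor(2.0, omega))

    def test_matches_fine_histogram(self, four_component_mixture):
        """Vectorial sum equals the phasor of the finely discretized expected
        histogram."""
        meta = AcquisitionMeta(n_bins=8192)
        decay = generate_decay(four_component_mixture, 1e6, meta)
        p = pixel_phasor(decay, 1)
        g, s = mixture_phasor(four_component_mixture, meta.omega(1))
        assert (p.g, p.s) == pytest.approx((g, s), abs=1e-3)

    def test_inside_convex_hull(self, four_component_mixture):
        omega = AcquisitionMeta().omega(1)
        g, s = mixture_phasor(four_component_mixture, omega)
        assert _circle_residual(g, s) < 0  # strictly inside for >1 component
        assert 0 < g < 1 and 0 < s <= 0.5


class TestPixelPhasor:
    def test_single_bin_histogram(self, meta):
        counts = np.zeros(meta.n_bins)
        counts[0] = 1000
        p = pixel_phasor(DecayHistogram(counts, meta), 1)
        t0 = meta.bin_centers_ns()[0]
        omega = meta.omega(1)
        assert (p.g, p.s) == pytest.approx((np.cos(omega * t0), np.sin(omega * t0)))
        assert p.g == pytest.approx(1.0, abs=1e-3)

    def test_omega_tau_one_fine_bins(self):
        """Expected decay with omega*tau = 1 lands at (0.5, 0.5)."""
        meta = AcquisitionMeta(n_bins=4096)
        tau = 1.0 / meta.omega(1)
        decay = generate_decay(LifetimeMixture((tau,), (1.0,)), 1e6, meta)
        p = pixel_phasor(decay, 1)
        assert (p.g, p.s) == pytest.approx((0.5, 0.5), abs=1e-3)

    def test_uniform_histogram_at_origin(self, meta):
        p = pixel_phasor(DecayHistogram(np.ones(meta.n_bins), meta), 1)
        assert (p.g, p.s) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_empty_histogram_rejected(self, meta):
        with pytest.raises(ValueError):
            pixel_phasor(DecayHistogram(np.zeros(meta.n_bins), meta), 1)

    def test_bad_harmonic_rejected(self, meta):
        with pytest.raises(ValueError):
            pixel_phasor(DecayHistogram(np.ones(meta.n_bins), meta), 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=16, max_size=16))
    def test_modulus_bounded_by_one(self, counts):
        """Triangle inequality: any nonnegative histogram has |(g, s)| <= 1."""
        if sum(counts) == 0:
            return
        meta = AcquisitionMeta(n_bins=16)
        p = pixel_phasor(DecayHistogram(np.array(counts, dtype=float), meta), 1)
        assert p.modulus <= 1.0 + 1e-9

    def test_linearity_photon_weighted_mean(self, meta, rng):
        """The phasor of a summed histogram is the photon-weighted mean of
        the phasors (exact by construction)."""
        for _ in range(20):
            a = rng.poisson(5.0, meta.n_bins).astype(float) + 1e-9
            b = rng.poisson(20.0, meta.n_bins).astype(float) + 1e-9
            pa = pixel_phasor(DecayHistogram(a, meta), 1)
            pb = pixel_phasor(DecayHistogram(b, meta), 1)
            pab = pixel_phasor(DecayHistogram(a + b, meta), 1)
            w = pa.photons / (pa.photons + pb.photons)
            assert pab.g == pytest.approx(w * pa.g + (1 - w) * pb.g, abs=1e-12)
            assert pab.s == pytest.approx(w * pa.s + (1 - w) * pb.s, abs=1e-12)


class TestPhasorImage:
    def _uniform_image(self, meta, rng, shape=(5, 5)):
        decay = rng.poisson(30.0, meta.n_bins)
        counts = np.broadcast_to(decay, (*shape, meta.n_bins)).copy()
        return TCSPCImage(counts, meta)

    def test_uniform_image_gives_constant_planes(self, meta, rng):
        img = self._uniform_image(meta, rng)
        valid = PixelMask(np.ones((5, 5), dtype=bool))
        ph = phasor_image(img, valid, 1)
        assert np.allclose(ph.g, ph.g[0, 0]) and np.allclose(ph.s, ph.s[0, 0])

    def test_spot_check_against_pixel_phasor(self, small_image, rng):
        valid = PixelMask(np.ones((8, 8), dtype=bool))
        ph = phasor_image(small_image, valid, 2)
        for _ in range(10):
            i, j = rng.integers(0, 8, 2)
            p = pixel_phasor(small_image.decay_at(i, j), 2)
            assert ph.g[i, j] == pytest.approx(p.g, abs=1e-12)
            assert ph.s[i, j] == pytest.approx(p.s, abs=1e-12)

    def test_second_harmonic_stays_on_circle(self):
        """A single-exponential expected decay maps onto the universal circle
        at both harmonics (within discretization error)."""
        meta = AcquisitionMeta(n_bins=4096)
        decay = generate_decay(LifetimeMixture((1.5,), (1.0,)), 1e6, meta)
        counts = np.broadcast_to(np.round(decay.counts).astype(int), (2, 2, meta.n_bins))
        img = TCSPCImage(counts.copy(), meta)
        valid = PixelMask(np.ones((2, 2), dtype=bool))
        for k in (1, 2):
            ph = phasor_image(img, valid, k)
            assert _circle_residual(ph.g[0, 0], ph.s[0, 0]) == pytest.approx(0.0, abs=1e-4)

    def test_no_valid_pixels_rejected(self, small_image):
        with pytest.raises(ValueError):
            phasor_image(small_image, PixelMask(np.zeros((8, 8), dtype=bool)), 1)


class TestCalibration:
    def test_identity_when_measured_equals_theory(self, meta):
        ref_model = LifetimeMixture((0.4,), (1.0,))
        g, s = mixture_phasor(ref_model, meta.omega(1))
        from flimphasor import PhasorPoint

        tr = calibrate(PhasorPoint(g, s, 1), ref_model, 1, meta)
        assert tr.phase_shift == pytest.approx(0.0, abs=1e-12)
        assert tr.modulation_scale == pytest.approx(1.0, abs=1e-12)

    def test_maps_measured_reference_onto_theory(self, meta):
        from flimphasor import PhasorPoint

        ref_model = LifetimeMixture((0.4,), (1.0,))
        measured = PhasorPoint(0.7, 0.2, 1)
        tr = calibrate(measured, ref_model, 1, meta)
        out = tr.apply_point(measured)
        assert (out.g, out.s) == pytest.approx(mixture_phasor(ref_model, meta.omega(1)))

    def test_phase_only_mode_preserves_modulus(self, meta):
        from flimphasor import PhasorPoint

        measured = PhasorPoint(0.7, 0.2, 1)
        tr = calibrate(measured, LifetimeMixture((0.4,), (1.0,)), 1, meta,
                       correction="phase")
        assert tr.modulation_scale == 1.0
        out = tr.apply_point(measured)
        assert np.hypot(out.g, out.s) == pytest.approx(measured.modulus, abs=1e-12)

    def test_recovers_instrumental_distortion(self, meta, rng):
        """With the reference standard passed through the same IRF offset and
        TAC truncation, a known single-exponential sample calibrates back to
        its closed-form circle point."""
        irf = GaussianIRF(fwhm_ns=0.2, offset_ns=0.5)
        ref_model = LifetimeMixture((0.4,), (1.0,))
        ref = apply_tac_truncation(
            generate_decay(ref_model, 1e6, meta, irf, "sampled", rng), 5
        )
        tr = calibrate(pixel_phasor(ref, 1), ref_model, 1, meta)
        sample = apply_tac_truncation(
            generate_decay(LifetimeMixture((2.0,), (1.0,)), 1e6, meta, irf,
                           "sampled", rng), 5
        )
        cal = tr.apply_point(pixel_phasor(sample, 1))
        g, s = single_exp_phasor(2.0, meta.omega(1))
        assert np.hypot(cal.g - g, cal.s - s) < 0.01


class TestApplyCalibration:
    def _image(self, rng):
        g = rng.uniform(0.2, 0.8, (4, 4))
        s = rng.uniform(0.1, 0.4, (4, 4))
        return PhasorImage(g, s, PixelMask(np.ones((4, 4), dtype=bool)), 1)

    def test_identity_transform(self, rng):
        img = self._image(rng)
        out = apply_calibration(img, CalibrationTransform(0.0, 1.0, 1))
        np.testing.assert_allclose(out.g, img.g)
        assert out.calibrated

    def test_pure_rotation_preserves_modulus(self, rng):
        img = self._image(rng)
        out = apply_calibration(img, CalibrationTransform(0.3, 1.0, 1))
        np.testing.assert_allclose(
            np.hypot(out.g, out.s), np.hypot(img.g, img.s), atol=1e-12
        )

    def test_matches_hand_computed_product(self, rng):
        img = self._image(rng)
        tr = CalibrationTransform(0.25, 1.3, 1)
        out = apply_calibration(img, tr)
        z = complex(img.g[1, 2], img.s[1, 2]) * 1.3 * np.exp(0.25j)
        assert out.g[1, 2] == pytest.approx(z.real, abs=1e-12)
        assert out.s[1, 2] == pytest.approx(z.imag, abs=1e-12)

    def test_harmonic_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_calibration(self._image(rng), CalibrationTransform(0.0, 1.0, 2))


class TestAggregateMeasurement:
    def test_mean_matches_brute_force(self, rng):
        g = rng.uniform(0, 1, (6, 6))
        s = rng.uniform(0, 0.5, (6, 6))
        valid = PixelMask(rng.random((6, 6)) > 0.3)
        img = PhasorImage(g, s, PixelMask(np.ones((6, 6), dtype=bool)), 1)
        m = aggregate_measurement({1: img}, valid, 0.2, "baseline")
        assert m.phasors[1][0] == pytest.approx(g[valid.include].mean(), abs=1e-12)
        assert m.phasors[1][1] == pytest.approx(s[valid.include].mean(), abs=1e-12)
        assert m.n_valid_pixels == valid.n_selected

    def test_single_pixel_degenerate(self):
        g = np.full((3, 3), 0.4)
        g[1, 1] = 0.9
        img = PhasorImage(g, np.full((3, 3), 0.2), PixelMask(np.ones((3, 3), bool)), 1)
        only = np.zeros((3, 3), dtype=bool)
        only[1, 1] = True
        m = aggregate_measurement({1: img}, PixelMask(only), 0.0, "c")
        assert m.phasors[1] == pytest.approx((0.9, 0.2))

    def test_no_valid_pixels_rejected(self):
        img = PhasorImage(np.ones((2, 2)), np.ones((2, 2)),
                          PixelMask(np.ones((2, 2), bool)), 1)
        with pytest.raises(ValueError):
            aggregate_measurement({1: img}, PixelMask(np.zeros((2, 2), bool)), 0.0, "c")


class TestUniversalCircle:
    def test_points_satisfy_circle_equation(self):
        pts = universal_circle(500)
        np.testing.assert_allclose(_circle_residual(pts[:, 0], pts[:, 1]), 0, atol=1e-12)
        assert np.all(pts[:, 1] >= -1e-15)

    def test_endpoints_and_apex(self):
        pts = universal_circle(1001)
        np.testing.assert_allclose(pts[0], [0, 0], atol=1e-12)
        np.testing.assert_allclose(pts[-1], [1, 0], atol=1e-12)
        assert pts[:, 1].max() == pytest.approx(0.5, abs=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            universal_circle(1)
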