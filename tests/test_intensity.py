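import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import centrotrack as ct
from centrotrack.intensity import FrapFitError, _roi_mean


class TestLineProfile:
    def test_constant_image(self):
        img = np.full((64, 64), 100.0)
        prof = ct.line_profile(img, (1.0, 3.0), (6.0, 3.0), pixel_size=0.1)
        np.testing.assert_allclose(prof.raw, 100.0)

    def test_five_um_at_tenth_step_has_51_samples(self):
        img = np.zeros((64, 64))
        prof = ct.line_profile(img, (0.5, 3.0), (5.5, 3.0), pixel_size=0.1, step=0.1)
        assert len(prof.positions) == 51
        assert prof.positions[-1] == pytest.approx(5.0)

    def test_gaussian_centered_between_centrioles_peaks_mid_profile(self):
        # a centrosomal-protein blob at the pair midpoint, profiled along the
        # centriolar axis, peaks at the middle of the 5-um line
        px = 0.1
        rr, cc = np.mgrid[0:80, 0:80]
        mid = np.array([4.0, 4.0])  # um
        img = 100.0 * np.exp(
            -((cc * px - mid[0]) ** 2 + (rr * px - mid[1]) ** 2) / (2 * 0.4**2)
        )
        u = np.array([np.cos(0.5), np.sin(0.5)])
        a, b = mid - 2.5 * u, mid + 2.5 * u
        prof = ct.line_profile(img, a, b, px, step=0.1, expected_length=5.0)
        peak_pos = prof.positions[np.argmax(prof.raw)]
        assert peak_pos == pytest.approx(2.5, abs=0.1)

    def test_line_exiting_image_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ct.line_profile(np.zeros((32, 32)), (0.0, 0.0), (-5.0, 0.0), 0.1)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ct.line_profile(np.zeros((64, 64)), (1.0, 1.0), (3.0, 1.0), 0.1,
                            expected_length=5.0)


class TestNormalizeProfile:
    def test_constant_profile_normalizes_to_one(self):
        prof = ct.LineProfile(positions=np.linspace(0, 5, 51), raw=np.full(51, 77.0))
        assert np.allclose(ct.normalize_profile(prof).normalized, 1.0)

    def test_tails_fifty_peak_two_hundred(self):
        raw = np.full(51, 50.0)
        raw[25] = 200.0
        prof = ct.LineProfile(positions=np.linspace(0, 5, 51), raw=raw)
        norm = ct.normalize_profile(prof, tail_count=4).normalized
        assert norm[25] == pytest.approx(4.0)

    def test_too_few_samples_rejected(self):
        prof = ct.LineProfile(positions=np.arange(7.0), raw=np.ones(7))
        with pytest.raises(ValueError):
            ct.normalize_profile(prof, tail_count=4)

    @given(st.floats(0.5, 20))
    @settings(max_examples=30, derandomize=True)
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(9)
        raw = rng.uniform(10, 100, 51)
        prof = ct.LineProfile(positions=np.linspace(0, 5, 51), raw=raw)
        scaled = ct.LineProfile(positions=prof.positions, raw=raw * gain)
        np.testing.assert_allclose(
            ct.normalize_profile(prof).normalized,
            ct.normalize_profile(scaled).normalized,
            rtol=1e-9,
        )


class TestCentrosomeIntensityRatio:
    def _image(self, v1, v2, pixel_size=0.05):
        img = np.zeros((80, 80))
        rr, cc = np.mgrid[0:80, 0:80]  # disks at (1.0, 1.0) and (3.0, 3.0) um
        img[(cc * pixel_size - 1.0) ** 2 + (rr * pixel_size - 1.0) ** 2 <= 0.35**2] = v1
        img[(cc * pixel_size - 3.0) ** 2 + (rr * pixel_size - 3.0) ** 2 <= 0.35**2] = v2
        return img

    def test_equal_means_ratio_one(self):
        img = self._image(100.0, 100.0)
        assert ct.centrosome_intensity_ratio(img, (1.0, 1.0), (3.0, 3.0), 0.05) == 1.0

    def test_higher_value_is_divisor(self):
        img = self._image(100.0, 200.0)
        r = ct.centrosome_intensity_ratio(img, (1.0, 1.0), (3.0, 3.0), 0.05)
        assert r == pytest.approx(0.5)
        # symmetric in the two positions
        r2 = ct.centrosome_intensity_ratio(img, (3.0, 3.0), (1.0, 1.0), 0.05)
        assert r2 == pytest.approx(r)

    def test_zero_signal_roi_rejected(self):
        img = self._image(100.0, 0.0)
        with pytest.raises(ValueError):
            ct.centrosome_intensity_ratio(img, (1.0, 1.0), (3.0, 3.0), 0.05)

    def test_overlapping_rois_warn(self):
        img = self._image(100.0, 100.0)
        with pytest.warns(UserWarning, match="overlap"):
            ct.centrosome_intensity_ratio(img, (1.0, 1.0), (1.2, 1.0), 0.05)

    def test_discretized_roi_area_converges_to_circle(self):
        # pixel-center membership: area -> pi r^2 as pixel_size -> 0
        radius = 0.35
        errs = []
        for px, tol in [(0.05, 0.06), (0.01, 0.005)]:
            n = int(2 * radius / px) + 6
            img = np.ones((n, n))
            c = (n // 2) * px
            _, member = _roi_mean(img, (c, c), radius, px)
            area = member.sum() * px**2
            assert area == pytest.approx(np.pi * radius**2, rel=tol)
            errs.append(abs(area - np.pi * radius**2))
        assert errs[-1] < errs[0]


class TestFrapNormalize:
    def test_prebleach_mean_is_one(self):
        b = np.array([110.0] * 5 + [30.0] * 15)
        r = np.full(20, 110.0)
        curve = ct.frap_normalize(b, r, background=10.0, pre_bleach_count=5)
        assert curve.normalized[:5].mean() == pytest.approx(1.0)

    def test_immobile_flat_at_bleach_depth(self):
        b = np.array([110.0] * 5 + [35.0] * 15)
        r = np.full(20, 110.0)
        curve = ct.frap_normalize(b, r, 10.0, 5)
        np.testing.assert_allclose(curve.normalized[5:], 0.25)

    def test_reference_below_background_rejected(self):
        with pytest.raises(ValueError):
            ct.frap_normalize(np.ones(10), np.full(10, 5.0), background=10.0,
                              pre_bleach_count=2)

    def test_gain_invariance(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(50, 150, 30)
        r = rng.uniform(100, 150, 30)
        c1 = ct.frap_normalize(b, r, 10.0, 5)
        c2 = ct.frap_normalize(3.0 * b - 20.0, 3.0 * r - 20.0, 3.0 * 10.0 - 20.0, 5)
        np.testing.assert_allclose(c1.normalized, c2.normalized, rtol=1e-9)


class TestFrapHalftime:
    def _curve(self, mobile, half_time, n_post=120, f0=0.0):
        t = np.arange(5 + n_post, dtype=float)
        post = f0 + mobile * (1 - f0) * (1 - 0.5 ** (np.arange(n_post) / half_time))
        vals = np.concatenate([np.ones(5), post])
        return ct.FrapCurve(times=t, raw_bleached=vals, raw_reference=np.ones_like(vals),
                            background=0.0, normalized=vals, bleach_frame=5)

    def test_noiseless_recovery(self):
        ht, mf = ct.frap_halftime(self._curve(0.66, 20.0))
        assert ht == pytest.approx(20.0, abs=0.5)
        assert mf == pytest.approx(0.66, abs=0.01)

    def test_flat_curve_zero_mobile(self):
        _, mf = ct.frap_halftime(self._curve(0.0, 20.0))
        assert mf == 0.0

    def test_decreasing_curve_fails(self):
        t = np.arange(25, dtype=float)
        vals = np.concatenate([np.ones(5), 0.8 - 0.02 * np.arange(20)])
        curve = ct.FrapCurve(times=t, raw_bleached=vals, raw_reference=np.ones_like(vals),
                             background=0.0, normalized=vals, bleach_frame=5)
        with pytest.raises(FrapFitError):
            ct.frap_halftime(curve)

    def test_end_to_end_from_synthetic_movie(self):
        movie, truth = ct.make_frap_series(mobile_fraction=0.66, half_time=20.0, n_post=300)
        ch = movie.channel("frap")
        px = movie.pixel_size
        h, w = ch.shape[1:]
        rr, cc = np.mgrid[0:h, 0:w]

        def roi_series(roi):
            (c, rad) = roi
            m = ((cc * px - c[0]) ** 2 + (rr * px - c[1]) ** 2) <= rad**2
            return ch[:, m].mean(axis=1)

        curve = ct.frap_normalize(
            roi_series(truth.roi_bleach), roi_series(truth.roi_reference),
            truth.background, truth.bleach_frame,
            times=np.arange(ch.shape[0]) * movie.frame_interval,
        )
        assert curve.normalized[-5:].mean() == pytest.approx(0.66, abs=0.01)
        ht, mf = ct.frap_halftime(curve)
        assert ht == pytest.approx(20.0, abs=0.5)
        assert mf == pytest.approx(0.66, abs=0.01)
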