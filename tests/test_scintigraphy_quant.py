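"""Scintigraphic correction chain: smoothing, background, decay, attenuation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerodep.scintigraphy_quant import (
    TC99M_HALF_LIFE_S,
    CorrectionSet,
    PlanarImage,
    RegionalCounts,
    ROIMask,
    attenuation_factor_from_calibration,
    decay_correct,
    quantify_regions,
    smooth_9point,
    subtract_background,
)
from aerodep.synthetic_data import PhantomTruth, corrections_for, gen_phantom, phantom_geometry


def make_image(counts, duration=120.0, start=0.0):
    return PlanarImage(np.asarray(counts, dtype=float), duration, start)


class TestSmooth9Point:
    def test_constant_image_unchanged(self):
        img = make_image(np.full((16, 16), 7.0))
        out = smooth_9point(img)
        np.testing.assert_allclose(out.counts, 7.0)
        assert out.counts.sum() == pytest.approx(img.counts.sum())

    def test_center_spike_spreads_to_mean(self):
        img = make_image([[0, 0, 0], [0, 9, 0], [0, 0, 0]])
        np.testing.assert_allclose(smooth_9point(img).counts, 1.0)

    def test_variance_reduced_ninefold_in_flat_interior(self):
        rng = np.random.default_rng(3)
        img = make_image(rng.poisson(1000.0, size=(256, 256)))
        out = smooth_9point(img)
        interior = out.counts[5:-5, 5:-5]
        # variance of the mean of 9 iid pixels (neighbouring outputs share
        # pixels, but the marginal per-pixel variance is still var/9)
        assert interior.var() == pytest.approx(1000.0 / 9.0, rel=0.1)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            smooth_9point(make_image([[1.0, 2.0]]))

    def test_custom_kernel_normalized(self):
        img = make_image(np.full((8, 8), 4.0))
        kernel = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float)
        np.testing.assert_allclose(smooth_9point(img, kernel).counts, 4.0)


class TestSubtractBackground:
    def test_plain_subtraction(self):
        assert subtract_background(1000.0, 100, 0.01, 100.0) == 900.0

    def test_clamped_at_zero_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert subtract_background(50.0, 100, 0.01, 100.0) == 0.0

    def test_phantom_background_recovery(self):
        """Net ROI counts on a background-only phantom stay within 3x the
        Poisson standard error of zero."""
        geom = phantom_geometry()
        truth = PhantomTruth(
            activities_mbq={"ET": 0.0, "TH": 0.0}, background_rate=0.01, seed=11
        )
        img, masks = gen_phantom(truth)
        regions = quantify_regions(img, masks, corrections_for(truth))
        for r in regions:
            expected_bg = 0.01 * geom[r.region].sum() * 120.0
            assert r.net <= 3.0 * np.sqrt(expected_bg)


class TestDecayCorrect:
    def test_zero_elapsed_identity(self):
        assert decay_correct(1234.0, 0.0, TC99M_HALF_LIFE_S) == 1234.0

    def test_one_half_life_doubles(self):
        assert decay_correct(1000.0, TC99M_HALF_LIFE_S, TC99M_HALF_LIFE_S) == 2000.0

    @given(
        counts=st.floats(min_value=0, max_value=1e9),
        t=st.floats(min_value=-1e5, max_value=1e5),
    )
    @settings(max_examples=50, deadline=None)
    def test_invertibility(self, counts, t):
        once = decay_correct(counts, t, TC99M_HALF_LIFE_S)
        back = decay_correct(once, -t, TC99M_HALF_LIFE_S)
        assert back == pytest.approx(counts, rel=1e-12, abs=1e-9)

    def test_negative_half_life_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(10.0, 5.0, -1.0)


class TestAttenuationFactor:
    def _measured(self, corrected):
        return RegionalCounts("CALIBRATION", corrected, corrected, corrected, 0.03)

    def test_unity_when_observed_equals_expected(self):
        assert attenuation_factor_from_calibration(
            self._measured(6000.0), 1.0, 50.0, 120.0
        ) == pytest.approx(1.0)

    def test_two_when_observed_halved(self):
        assert attenuation_factor_from_calibration(
            self._measured(3000.0), 1.0, 50.0, 120.0
        ) == pytest.approx(2.0)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            attenuation_factor_from_calibration(self._measured(0.0), 1.0, 50.0, 120.0)

    def test_subunity_factor_warns(self):
        with pytest.warns(UserWarning, match="factor"):
            attenuation_factor_from_calibration(
                self._measured(12000.0), 1.0, 50.0, 120.0
            )

    def test_exponential_attenuation_recovered_from_phantom(self):
        """A phantom attenuated by e^-0.5 yields a factor within 3% of
        e^0.5 = 1.649 when calibrated against the known activity."""
        mu_d = 0.5
        truth = PhantomTruth(
            activities_mbq={"ET": 1.0, "TH": 0.5},
            attenuation={"ET": float(np.exp(mu_d)), "TH": 1.0},
            background_rate=0.0,
            seed=5,
        )
        img, masks = gen_phantom(truth)
        # quantify with the chain minus attenuation
        no_atten = CorrectionSet(half_life_seconds=truth.half_life_seconds)
        observed = {
            r.region: r for r in quantify_regions(img, masks, no_atten)
        }
        factor = attenuation_factor_from_calibration(
            observed["ET"], 1.0, truth.sensitivity_cps_per_mbq, 120.0
        )
        assert factor == pytest.approx(np.exp(mu_d), rel=0.03)


class TestQuantifyRegions:
    def _phantom(self, et=3.7, th=1.3, **kw):
        truth = PhantomTruth(activities_mbq={"ET": et, "TH": th}, **kw)
        img, masks = gen_phantom(truth)
        return truth, img, masks

    def test_recovers_ground_truth_shares(self):
        truth, img, masks = self._phantom(seed=2)
        regions = {r.region: r for r in quantify_regions(img, masks, corrections_for(truth))}
        total = regions["ET"].corrected + regions["TH"].corrected
        assert regions["ET"].corrected / total == pytest.approx(
            3.7 / 5.0, abs=0.03
        )

    def test_identity_chain_returns_smoothed_sums(self):
        truth, img, masks = self._phantom(background_rate=0.0, seed=3)
        corr = CorrectionSet()  # factors 1, no background, reference at start
        smoothed = smooth_9point(img)
        regions = quantify_regions(img, masks, corr)
        for r in regions:
            roi = next(m for m in masks if m.label == r.region)
            assert r.corrected == pytest.approx(
                smoothed.counts[roi.mask].sum(), rel=1e-9
            )

    def test_pure_background_clamps_to_zero(self):
        truth = PhantomTruth(
            activities_mbq={"ET": 0.0, "TH": 0.0}, background_rate=0.05,
            noise_model="none",
        )
        img, masks = gen_phantom(truth)
        regions = quantify_regions(img, masks, corrections_for(truth))
        for r in regions:
            assert r.net == pytest.approx(0.0, abs=1e-6)

    def test_decay_and_attenuation_commute(self):
        """Both corrections are multiplicative, so applying them in either
        order yields identical corrected counts."""
        truth, img, masks = self._phantom(seed=4, acquisition_start=600.0)
        corr = corrections_for(truth)
        regions = quantify_regions(img, masks, corr)
        for r in regions:
            factor = corr.attenuation_factor[r.region]
            decay_then_atten = decay_correct(r.net, 600.0, corr.half_life_seconds) * factor
            atten_then_decay = decay_correct(r.net * factor, 600.0, corr.half_life_seconds)
            assert decay_then_atten == pytest.approx(atten_then_decay, rel=1e-12)
            assert r.corrected == pytest.approx(decay_then_atten, rel=1e-12)

    def test_doubling_duration_doubles_counts_not_rate(self):
        truth = PhantomTruth(
            activities_mbq={"ET": 2.0, "TH": 1.0}, background_rate=0.0,
            noise_model="none",
        )
        img1, masks = gen_phantom(truth)
        truth2 = PhantomTruth(
            activities_mbq={"ET": 2.0, "TH": 1.0}, background_rate=0.0,
            noise_model="none", acquisition_seconds=240.0,
        )
        img2, _ = gen_phantom(truth2)
        corr = corrections_for(truth)
        r1 = {r.region: r for r in quantify_regions(img1, masks, corr)}
        r2 = {r.region: r for r in quantify_regions(img2, masks, corr)}
        for label in ("ET", "TH"):
            assert r2[label].raw == pytest.approx(2 * r1[label].raw, rel=1e-9)
            assert r2[label].corrected / 240.0 == pytest.approx(
                r1[label].corrected / 120.0, rel=1e-9
            )

    def test_missing_mask_rejected(self):
        truth, img, masks = self._phantom()
        just_et = [m for m in masks if m.label != "TH"]
        with pytest.raises(ValueError, match="TH"):
            quantify_regions(img, just_et, corrections_for(truth))

    def test_incongruent_mask_rejected(self):
        truth, img, masks = self._phantom()
        bad = [ROIMask(m.label, m.mask[:, :100]) for m in masks]
        with pytest.raises(ValueError, match="shape"):
            quantify_regions(img, bad, corrections_for(truth))

    def test_relative_accuracy_reflects_count_level(self):
        truth, img, masks = self._phantom(seed=9)
        regions = quantify_regions(img, masks, corrections_for(truth))
        for r in regions:
            assert r.relative_accuracy == pytest.approx(1 / np.sqrt(r.net))
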