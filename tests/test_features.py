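import dataclasses

import numpy as np
import pytest

from oracles import pair_features_pixel_loop
from thermasym import (
    FeatureVector,
    PipelineConfig,
    averaged_features,
    count_exceeding,
    extract_features,
    is_asymmetric,
    make_face_phantom,
    make_mouth_phantom,
    region_summary,
)
from thermasym.exceptions import ThermasymError
from thermasym.features import FEATURE_NAMES
from thermasym.symmetry import RegionPair


def make_pair(temps_a, temps_b) -> RegionPair:
    temps_a = np.asarray(temps_a, dtype=float)
    temps_b = np.asarray(temps_b, dtype=float)
    pix_a = np.column_stack([np.zeros(len(temps_a), int), np.arange(len(temps_a))])
    pix_b = np.column_stack([np.ones(len(temps_b), int), np.arange(len(temps_b))])
    return RegionPair(side_a_temps=temps_a, side_b_temps=temps_b,
                      side_a_pixels=pix_a, side_b_pixels=pix_b)


def random_pair(rng) -> RegionPair:
    na, nb = rng.integers(2, 40, size=2)
    return make_pair(
        rng.uniform(30, 36, na).round(3), rng.uniform(30, 36, nb).round(3)
    )


class TestRegionSummary:
    @pytest.mark.parametrize(
        "temps,expected",
        [([33, 33, 33], (33, 33, 0)), ([32, 34], (33, 34, 1))],
    )
    def test_hand_cases(self, temps, expected):
        assert region_summary(np.array(temps, float)) == expected

    def test_empty_collection_rejected(self):
        with pytest.raises(ThermasymError):
            region_summary(np.array([]))

    def test_agrees_with_brute_force(self, rng):
        for _ in range(50):
            temps = rng.uniform(25, 40, rng.integers(1, 60))
            mean, mx, mad = region_summary(temps)
            mean_o = sum(temps) / len(temps)
            mad_o = sum(abs(t - mean_o) for t in temps) / len(temps)
            assert abs(mean - mean_o) < 1e-12
            assert mx == max(temps)
            assert abs(mad - mad_o) < 1e-12


class TestCountExceeding:
    def test_uniformly_warmer_side_counts_every_pixel(self):
        pair = make_pair([34.0] * 7, [33.5] * 5)
        assert count_exceeding(pair, 0.4) == 7  # every 34.0 > 33.5 + 0.4

    def test_identical_sides_count_zero(self):
        pair = make_pair([33.0, 34.0], [33.0, 34.0])
        assert count_exceeding(pair, 0.4) == 0

    def test_two_pixel_hand_count(self):
        pair = make_pair([34.0, 33.8], [33.7, 33.6])
        # cut is 33.7 + 0.4 = 34.1; neither 34.0 nor 33.8 exceeds it
        assert count_exceeding(pair, 0.4) == 0


class TestExtractFeatures:
    def test_constant_regions_closed_form(self, config):
        face = make_pair([34.0] * 100, [33.5] * 100)
        mouth = make_pair([35.6] * 100, [35.0] * 100)
        fv = extract_features(face, mouth, config)
        expected = dict(dTf=0.5, dTfmax=0.5, nf=100, dDEVf=0.0,
                        dTm=0.6, dTmmax=0.6, nm=100, dDEVm=0.0)
        for name, val in expected.items():
            assert getattr(fv, name) == pytest.approx(val, abs=1e-12)

    def test_symmetric_pairs_give_zero_vector(self, config):
        pair = make_pair([33.0, 34.0, 35.0], [35.0, 33.0, 34.0])
        fv = extract_features(pair, pair, config)
        assert np.all(fv.as_array() == 0)

    def test_agrees_with_pixel_loop_oracle(self, config, rng):
        for _ in range(50):
            face, mouth = random_pair(rng), random_pair(rng)
            fv = extract_features(face, mouth, config)
            face_exp = pair_features_pixel_loop(
                face.side_a_temps, face.side_b_temps, config.delta_t_threshold_c)
            mouth_exp = pair_features_pixel_loop(
                mouth.side_a_temps, mouth.side_b_temps, config.delta_t_threshold_c)
            np.testing.assert_allclose(
                fv.as_array(), np.r_[face_exp, mouth_exp], atol=1e-12)

    def test_side_swap_invariance(self, config, rng):
        for _ in range(20):
            face, mouth = random_pair(rng), random_pair(rng)
            fv = extract_features(face, mouth, config)
            fv_swapped = extract_features(face.swapped(), mouth.swapped(), config)
            np.testing.assert_array_equal(fv.as_array(), fv_swapped.as_array())

    def test_offset_invariance(self, config, rng):
        face, mouth = random_pair(rng), random_pair(rng)
        shifted = [
            make_pair(p.side_a_temps + 2.5, p.side_b_temps + 2.5)
            for p in (face, mouth)
        ]
        fv0 = extract_features(face, mouth, config)
        fv1 = extract_features(*shifted, config)
        np.testing.assert_allclose(fv0.as_array(), fv1.as_array(), atol=1e-9)

    def test_mean_asymmetry_scales_with_deviations(self, config):
        """Scaling both sides' deviations from the joint mean scales dTf linearly."""
        a = np.array([33.0, 33.4, 33.8])
        b = np.array([33.2, 33.6, 34.0])
        joint = np.r_[a, b].mean()
        fv1 = extract_features(make_pair(a, b), make_pair(a, b), config)
        a2 = joint + 3 * (a - joint)
        b2 = joint + 3 * (b - joint)
        fv3 = extract_features(make_pair(a2, b2), make_pair(a2, b2), config)
        assert fv3.dTf == pytest.approx(3 * fv1.dTf, abs=1e-12)


class TestAveragedFeatures:
    def views(self, spec, amp=0.0):
        face_spec = spec
        if amp > 0:
            face_spec = dataclasses.replace(
                spec, lesion_amp_c=amp, lesion_center=(40.0, 62.0), lesion_radius_px=6.0)
        face, _ = make_face_phantom(face_spec)
        mouth, _ = make_mouth_phantom(spec)
        return face, mouth

    def test_zero_jitter_equals_single_estimate(self, small_spec, config):
        face, mouth = self.views(small_spec)
        cfg = config.replace(jitter_px=0.0)
        fv_avg = averaged_features(face, mouth, cfg, seed=1)
        fv_one = averaged_features(face, mouth, cfg.replace(n_estimates=1), seed=2)
        np.testing.assert_allclose(fv_avg.as_array(), fv_one.as_array(), atol=1e-12)

    def test_deterministic_given_seed(self, small_spec, config):
        spec = dataclasses.replace(small_spec, noise_sd_c=0.06, seed=5)
        face, mouth = self.views(spec)
        fv1 = averaged_features(face, mouth, config, seed=9)
        fv2 = averaged_features(face, mouth, config, seed=9)
        np.testing.assert_array_equal(fv1.as_array(), fv2.as_array())
        fv3 = averaged_features(face, mouth, config, seed=10)
        assert not np.array_equal(fv1.as_array(), fv3.as_array())

    def test_jittered_estimates_stay_consistent(self, small_spec, config):
        """On a noiseless phantom the five jittered estimates scatter tightly
        around the unjittered single-run value."""
        face, mouth = self.views(small_spec, amp=1.0)
        single = averaged_features(
            face, mouth, config.replace(n_estimates=1), seed=0)
        estimates = [
            averaged_features(face, mouth, config.replace(n_estimates=2), seed=s)
            for s in range(5)
        ]  # each = mean(single, one jittered estimate)
        arr = np.array([e.as_array() for e in estimates])
        sd = arr.std(axis=0)
        delta = np.abs(arr.mean(axis=0) - single.as_array())
        assert np.all(delta <= 3 * sd + 1e-9)

    def test_lesion_asymmetry_monotone_in_amplitude(self, small_spec, config):
        """Expected face asymmetry and exceedance count never decrease with
        lesion amplitude (20 noisy phantoms per amplitude, true-axis split)."""
        from thermasym.symmetry import AxisLine, convex_hull, split_regions
        from thermasym.edges import body_roi_mask, detect_edges

        amps = [0.0, 0.5, 1.0, 2.0]
        mean_dtf, mean_nf = [], []
        for amp in amps:
            dtfs, nfs = [], []
            for seed in range(20):
                spec = dataclasses.replace(small_spec, noise_sd_c=0.06, seed=seed)
                if amp > 0:
                    spec = dataclasses.replace(
                        spec, lesion_amp_c=amp, lesion_center=(40.0, 62.0),
                        lesion_radius_px=6.0)
                tg, truth = make_face_phantom(spec)
                hull = convex_hull(detect_edges(tg, config,
                                                body_roi_mask(tg, config)).points)
                axis = AxisLine(point=truth.axis_point, direction=truth.axis_direction)
                pair = split_regions(tg, hull, axis)
                fv = extract_features(pair, pair, config)
                dtfs.append(fv.dTf)
                nfs.append(fv.nf)
            mean_dtf.append(np.mean(dtfs))
            mean_nf.append(np.mean(nfs))
        assert mean_dtf == sorted(mean_dtf)
        assert mean_nf == sorted(mean_nf)


class TestAsymmetryRule:
    def fv(self, **kw):
        base = dict.fromkeys(FEATURE_NAMES, 0.0)
        base.update(kw)
        return FeatureVector(**base)

    def test_exactly_at_threshold_is_normal(self, config):
        assert not is_asymmetric(self.fv(dTf=0.40, dTm=0.40), config)

    def test_just_above_threshold_is_abnormal(self, config):
        assert is_asymmetric(self.fv(dTm=0.41), config)

    def test_tumor_group_mean_mouth_asymmetry_is_abnormal(self, config):
        # 0.46 °C is a typical lesion-group mouth asymmetry; well above 0.4
        assert is_asymmetric(self.fv(dTm=0.46, dTf=0.2), config)

    def test_zero_vector_is_normal(self, config):
        assert not is_asymmetric(self.fv(), config)

    def test_negative_feature_rejected(self):
        with pytest.raises(ThermasymError):
            self.fv(dTf=-0.1)
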