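import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgflap import (
    ELIGIBILITY_THRESHOLD,
    RPUMap,
    area_percent_ratio,
    assess_flap,
    assess_recording,
    compute_rpu,
    segment_hypoperfused,
    simulate_case,
)


def _rpu_from(values, breast):
    return compute_rpu(np.asarray(values, float), breast)


class TestComputeRpu:
    def test_uniform_roi_maps_to_100(self):
        breast = np.ones((4, 4), bool)
        rpu = _rpu_from(np.full((4, 4), 37.0), breast)
        assert np.all(rpu.values == 100.0)
        assert rpu.normalizer == 37.0

    def test_known_values(self):
        breast = np.zeros((1, 4), bool)
        breast[0, :3] = True
        intensity = np.array([[10.0, 50.0, 200.0, 999.0]])
        rpu = _rpu_from(intensity, breast)
        assert np.allclose(rpu.values[0, :3], [5.0, 25.0, 100.0])
        assert rpu.values[0, 3] == 0.0  # outside ROI

    def test_dropout_case_exact_rpu(self):
        case = simulate_case(height=64, width=64, target_dropout_fraction=15.0,
                             dropout_factor=0.2, seed=9)
        _, rpu = assess_recording(case.frames, case.breast_mask, case.nipple_mask)
        inside = case.breast_mask
        assert np.allclose(rpu.values[inside & case.truth_hypo_mask], 20.0)
        assert np.allclose(rpu.values[inside & ~case.truth_hypo_mask], 100.0)

    def test_zero_roi_rejected(self):
        breast = np.ones((3, 3), bool)
        with pytest.raises(ValueError, match="no perfusion signal"):
            _rpu_from(np.zeros((3, 3)), breast)
        with pytest.raises(ValueError):
            _rpu_from(np.ones((3, 3)), np.zeros((3, 3), bool))

    def test_sub_100_percentile_clips(self):
        breast = np.ones((1, 5), bool)
        rpu = compute_rpu(np.array([[1.0, 2.0, 3.0, 4.0, 100.0]]), breast,
                          percentile=50)
        assert rpu.normalizer == 3.0
        assert rpu.values.max() == 100.0  # brighter pixels clip at 100


class TestSegmentation:
    def test_well_perfused_flap_empty_mask(self):
        breast = np.ones((10, 10), bool)
        nipple = np.zeros_like(breast)
        rpu = _rpu_from(np.full((10, 10), 80.0), breast)
        mask = segment_hypoperfused(rpu, breast, nipple)
        assert not mask.any()

    def test_hypoperfusion_only_in_nipple_not_flagged(self):
        """Low perfusion confined to the nipple-areolar complex does not
        make a hypoperfused flap."""
        breast = np.ones((20, 20), bool)
        nipple = np.zeros_like(breast)
        nipple[8:14, 8:14] = True
        intensity = np.full((20, 20), 100.0)
        intensity[nipple] = 10.0  # RPU 10 in the nipple only
        rpu = _rpu_from(intensity, breast)
        assessment = assess_flap(rpu, breast, nipple)
        assert not assessment.is_hypoperfused_flap
        assert assessment.area_percent_ratio == 0.0

    def test_strict_inequality_brute_force_oracle(self):
        """segment_hypoperfused with min_component_px=1 equals a per-pixel
        reimplementation with strict < at the cutoff, on a random 32x32 map."""
        rng = np.random.default_rng(12)
        breast = rng.random((32, 32)) < 0.8
        breast[0, 0] = True
        nipple = breast & (rng.random((32, 32)) < 0.1)
        values = rng.choice([10.0, 29.9, 30.0, 30.1, 80.0, 100.0], (32, 32))
        values[~breast] = 0.0
        values.flat[np.flatnonzero(breast)[0]] = 100.0  # anchor the max
        rpu = RPUMap(values=values, normalizer=1.0, percentile_used=100.0)
        mask = segment_hypoperfused(rpu, breast, nipple, min_component_px=1)
        brute = np.zeros_like(breast)
        for i in range(32):
            for j in range(32):
                brute[i, j] = breast[i, j] and not nipple[i, j] and values[i, j] < 30.0
        assert np.array_equal(mask, brute)

    def test_small_components_removed(self):
        breast = np.ones((20, 20), bool)
        nipple = np.zeros_like(breast)
        intensity = np.full((20, 20), 100.0)
        intensity[2, 2] = 5.0             # 1-px speckle
        intensity[10:14, 10:14] = 5.0     # 16-px genuine region
        rpu = _rpu_from(intensity, breast)
        mask = segment_hypoperfused(rpu, breast, nipple, min_component_px=10)
        assert not mask[2, 2]
        assert mask[10:14, 10:14].all()
        raw = segment_hypoperfused(rpu, breast, nipple, min_component_px=1)
        assert raw[2, 2]

    def test_monotone_in_cutoff_and_component_size(self):
        case = simulate_case(height=64, width=64, target_dropout_fraction=20.0,
                             noise_sd=6.0, seed=21)
        _, rpu = assess_recording(case.frames, case.breast_mask, case.nipple_mask)
        ratios = [
            area_percent_ratio(
                segment_hypoperfused(rpu, case.breast_mask, case.nipple_mask,
                                     cutoff=c, min_component_px=1),
                case.breast_mask)
            for c in (10, 30, 60, 90)
        ]
        assert ratios == sorted(ratios)
        by_component = [
            area_percent_ratio(
                segment_hypoperfused(rpu, case.breast_mask, case.nipple_mask,
                                     min_component_px=m),
                case.breast_mask)
            for m in (1, 25, 100)
        ]
        assert by_component == sorted(by_component, reverse=True)


class TestAreaRatio:
    def test_trivial_values(self):
        breast = np.ones((10, 10), bool)
        assert area_percent_ratio(np.zeros_like(breast), breast) == 0.0
        assert area_percent_ratio(breast, breast) == 100.0

    def test_known_fraction(self):
        breast = np.zeros((100, 100), bool)
        breast[:100, :100] = True  # 10000 px
        hypo = np.zeros_like(breast)
        hypo.flat[:655] = True
        assert area_percent_ratio(hypo, breast) == pytest.approx(6.55)

    def test_errors(self):
        with pytest.raises(ValueError):
            area_percent_ratio(np.zeros((5, 5), bool), np.zeros((5, 5), bool))
        breast = np.zeros((5, 5), bool)
        breast[0, 0] = True
        bad = np.zeros((5, 5), bool)
        bad[4, 4] = True
        with pytest.raises(ValueError):
            area_percent_ratio(bad, breast)


class TestScaleInvariance:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e4,
                       allow_nan=False, allow_infinity=False))
    def test_rpu_and_ratio_invariant_to_intensity_scaling(self, k):
        """Multiplying all intensities by k > 0 leaves the RPU map, the
        hypoperfused mask and the area ratio unchanged."""
        rng = np.random.default_rng(5)
        breast = np.ones((24, 24), bool)
        nipple = np.zeros_like(breast)
        intensity = rng.uniform(1.0, 200.0, (24, 24))
        a = compute_rpu(intensity, breast)
        b = compute_rpu(intensity * k, breast)
        assert np.allclose(a.values, b.values)
        ma = segment_hypoperfused(a, breast, nipple, min_component_px=1)
        mb = segment_hypoperfused(b, breast, nipple, min_component_px=1)
        assert np.array_equal(ma, mb)


class TestRecoveryAndFlags:
    @pytest.mark.parametrize("fraction", [0.0, 10.0, 20.0, 38.0])
    def test_noise_free_recovery_is_exact(self, fraction):
        case = simulate_case(height=96, width=112, n_territories=14,
                             target_dropout_fraction=fraction, seed=33)
        assessment, _ = assess_recording(case.frames, case.breast_mask,
                                         case.nipple_mask)
        assert assessment.area_percent_ratio == case.truth_area_fraction
        assert assessment.is_hypoperfused_flap == (case.truth_area_fraction > 0)
        expected_flag = ("change_strategy_or_close_followup"
                         if case.truth_area_fraction > 15.0 else "proceed")
        assert assessment.decision_flag == expected_flag
        assert assessment.eligibility_excluded == (
            case.truth_area_fraction > ELIGIBILITY_THRESHOLD)

    def test_noisy_recovery_within_one_point(self):
        """At sensor noise of 5% of the plateau level the recovered ratio
        stays within one percentage point of the ground truth."""
        for seed in (1, 2, 3):
            case = simulate_case(height=96, width=112, n_territories=12,
                                 target_dropout_fraction=20.0,
                                 noise_sd=0.05 * 180.0, seed=seed)
            assessment, _ = assess_recording(case.frames, case.breast_mask,
                                             case.nipple_mask)
            assert assessment.area_percent_ratio == pytest.approx(
                case.truth_area_fraction, abs=1.0)
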