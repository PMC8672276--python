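"""Feature micro-examples, oracle equivalence and symmetry properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, freqz

from wearloc import (
    DeviceRecording,
    ParameterError,
    count_orientation_changes,
    extension_flexion_diff,
    extract_features,
    gravity_component,
    region_sequence,
    vertical_gyro_z,
    walking_gyro_energy,
    xy_gyro_correlation,
)
from wearloc.features import count_region_crossings

import oracles

FS = 59.5


class TestGravityComponent:
    def test_dc_gain_is_unity(self):
        out = gravity_component(np.full(2000, 1.0), FS)
        assert np.allclose(out, 1.0, atol=1e-9)

    def test_stopband_attenuation_matches_filter_response(self):
        # independent oracle: squared magnitude response of the designed
        # filter at 5 Hz (forward-backward application squares |H|)
        b, a = butter(4, 0.5, btype="low", fs=FS)
        _, h = freqz(b, a, worN=[5.0], fs=FS)
        expected_gain = np.abs(h[0]) ** 2
        t = np.arange(6000) / FS
        out = gravity_component(np.sin(2 * np.pi * 5.0 * t), FS)
        mid = out[1000:-1000]
        assert np.abs(mid).max() < 0.01
        assert np.abs(mid).max() <= expected_gain * 1.0 + 1e-6

    def test_superposition_recovers_dc_offset(self):
        t = np.arange(6000) / FS
        sig = 0.8 + np.sin(2 * np.pi * 5.0 * t)
        out = gravity_component(sig, FS)
        assert np.abs(out[1000:-1000] - 0.8).max() < 0.01

    def test_short_signal_returned_unfiltered(self):
        x = np.array([0.3, -0.2, 0.5])
        assert np.array_equal(gravity_component(x, FS), x)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            gravity_component(np.zeros(100), FS, cutoff=FS / 2)


class TestRegionSequence:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.5, 0.5, 0.1, -0.5], [1, 0, -1]),
            ([0.1, -0.1, 0.2], [0]),
            ([0.25, -0.25], [1, -1]),  # boundary values leave region 0
        ],
    )
    def test_examples(self, values, expected):
        assert region_sequence(np.array(values), 0.25).tolist() == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ParameterError):
            region_sequence(np.zeros(3), 0.0)


class TestOrientationChanges:
    def test_constant_signal_has_none(self):
        assert count_orientation_changes(np.full(3000, 1.0), FS) == 0

    def test_single_slow_traversal_counts_once(self):
        # one slow ramp from +1 g to -1 g crosses the centre region once
        n = 3000
        sig = np.linspace(1.0, -1.0, n)
        assert count_orientation_changes(sig, FS) == 1

    def test_hand_enumerated_region_triples(self):
        # distinct consecutive triples of [1,0,1,0,-1,0,1]:
        # (1,0,1) (0,1,0) (1,0,-1)* (0,-1,0) (-1,0,1)* -> 2 crossings
        regions = np.array([1, 0, 1, 0, -1, 0, 1])
        assert count_region_crossings(regions) == 2
        assert oracles.naive_count_crossings(regions.tolist()) == 2

    def test_direct_jump_without_centre_region_does_not_count(self):
        assert count_region_crossings(np.array([1, -1, 1, -1])) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        regions=st.lists(st.sampled_from([-1, 0, 1]), min_size=0, max_size=40)
    )
    def test_time_reversal_invariance(self, regions):
        # both crossing patterns are mirror images of each other, so the
        # count is preserved under reversal (of the collapsed sequence)
        collapsed = oracles.naive_collapse(regions)
        assert count_region_crossings(np.array(collapsed)) == count_region_crossings(
            np.array(collapsed[::-1])
        )


class TestWalkingGyroEnergy:
    def test_constant_above_threshold(self):
        gyro = np.tile([100.0, 0.0, 0.0], (50, 1))
        assert walking_gyro_energy(gyro) == pytest.approx(100.0)

    def test_magnitude_below_threshold_is_undefined(self):
        # |(30,30,30)| = sqrt(2700) ~ 51.96 < 70
        gyro = np.tile([30.0, 30.0, 30.0], (50, 1))
        assert np.sqrt(2700) < 70
        assert walking_gyro_energy(gyro) is None

    def test_only_qualifying_samples_averaged(self):
        gyro = np.zeros((100, 3))
        gyro[::2, 0] = 100.0
        assert walking_gyro_energy(gyro) == pytest.approx(100.0)


class TestXyGyroCorrelation:
    @pytest.mark.parametrize(
        "gx,gy,expected",
        [(30.0, 30.0, 900.0), (30.0, -30.0, -900.0)],
    )
    def test_constant_product(self, gx, gy, expected):
        gyro = np.tile([gx, gy, 0.0], (10, 1))
        assert xy_gyro_correlation(gyro) == pytest.approx(expected)

    def test_gate_applies_to_y_axis_only(self):
        # samples (gx, gy): (10,30) and (20,-30) pass |gy|>20; (5,10) not
        gyro = np.array([[10.0, 30.0, 0], [20.0, -30.0, 0], [5.0, 10.0, 0]])
        assert xy_gyro_correlation(gyro) == pytest.approx((300 - 600) / 2)

    def test_empty_gate_is_undefined(self):
        assert xy_gyro_correlation(np.zeros((10, 3))) is None


class TestExtensionFlexion:
    def test_vertical_gate_examples(self):
        assert vertical_gyro_z(np.ones(3), np.array([1.0, 2, 3])).tolist() == [1, 2, 3]
        assert vertical_gyro_z(np.zeros(3), np.array([1.0, 2, 3])).size == 0
        got = vertical_gyro_z(np.array([1.0, 0.0, -1.0]), np.array([10.0, 20, 30]))
        assert got.tolist() == [10, 30]

    def test_asymmetric_alternation(self):
        gz = np.tile([150.0, -120.0], 20)
        pos, neg, diff = extension_flexion_diff(np.ones(40), gz)
        assert (pos, neg, diff) == (150.0, 120.0, pytest.approx(30.0))

    def test_symmetric_alternation_has_zero_difference(self):
        gz = np.tile([150.0, -150.0], 20)
        assert extension_flexion_diff(np.ones(40), gz)[2] == pytest.approx(0.0)

    def test_never_vertical_is_undefined(self):
        gz = np.tile([150.0, -150.0], 20)
        assert extension_flexion_diff(np.zeros(40), gz) == (None, None, None)

    def test_one_sided_signal_leaves_gdiff_undefined(self):
        pos, neg, diff = extension_flexion_diff(np.ones(10), np.full(10, 150.0))
        assert pos == pytest.approx(150.0) and neg is None and diff is None


class TestExtractFeatures:
    def test_zero_motion_recording(self, params):
        rec = DeviceRecording(
            "still",
            acc=np.column_stack([np.ones(500), np.zeros(500), np.zeros(500)]),
            gyro=np.zeros((500, 3)),
        )
        fv = extract_features(rec, params)
        assert fv.orientation_changes == 0
        assert fv.gen is None and fv.cxy is None and fv.gdiff is None

    def test_deterministic(self, params, rng):
        from conftest import random_recording

        rec = random_recording(rng, 2000)
        assert extract_features(rec, params) == extract_features(rec, params)

    def test_left_shank_simulation_has_positive_gdiff(self, params, short_schedule):
        from wearloc import simulate_device

        fv = extract_features(simulate_device("LL", short_schedule, seed=5), params)
        assert fv.gdiff is not None and fv.gdiff > 0
        assert fv.gen is not None and fv.gen > 70


finite = {"allow_nan": False, "allow_infinity": False, "width": 64}


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 500))
    def test_all_features_match_naive_loops(self, seed, n):
        rng = np.random.default_rng(seed)
        gyro = rng.normal(0, 150, (n, 3))
        acc_x = rng.normal(0, 1.0, n)

        gen = walking_gyro_energy(gyro)
        gen_ref = oracles.naive_walking_energy(gyro.tolist())
        assert (gen is None) == (gen_ref is None)
        if gen is not None:
            assert gen == pytest.approx(gen_ref, rel=1e-12)

        cxy = xy_gyro_correlation(gyro)
        cxy_ref = oracles.naive_cxy(gyro.tolist())
        assert (cxy is None) == (cxy_ref is None)
        if cxy is not None:
            assert cxy == pytest.approx(cxy_ref, rel=1e-12, abs=1e-12)

        assert vertical_gyro_z(acc_x, gyro[:, 2]).tolist() == oracles.naive_gvert(
            acc_x.tolist(), gyro[:, 2].tolist()
        )
        got = extension_flexion_diff(acc_x, gyro[:, 2])
        ref = oracles.naive_extension_flexion(acc_x.tolist(), gyro[:, 2].tolist())
        for g, r in zip(got, ref):
            assert (g is None) == (r is None)
            if g is not None:
                assert g == pytest.approx(r, rel=1e-12)

        assert region_sequence(acc_x, 0.25).tolist() == oracles.naive_region_sequence(
            acc_x.tolist(), 0.25
        )


class TestSymmetries:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 300))
    def test_cxy_antisymmetric_in_x(self, seed, n):
        gyro = np.random.default_rng(seed).normal(0, 80, (n, 3))
        flipped = gyro.copy()
        flipped[:, 0] = -flipped[:, 0]
        a, b = xy_gyro_correlation(gyro), xy_gyro_correlation(flipped)
        assert (a is None) == (b is None)
        if a is not None:
            assert b == pytest.approx(-a, rel=1e-12, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 300))
    def test_gdiff_antisymmetric_in_z(self, seed, n):
        rng = np.random.default_rng(seed)
        acc_x = rng.normal(0, 1.0, n)
        gz = rng.normal(0, 200, n)
        pos, neg, diff = extension_flexion_diff(acc_x, gz)
        pos2, neg2, diff2 = extension_flexion_diff(acc_x, -gz)
        assert pos2 == (pytest.approx(neg) if neg is not None else None)
        assert neg2 == (pytest.approx(pos) if pos is not None else None)
        if diff is not None:
            assert diff2 == pytest.approx(-diff, abs=1e-12)

    def test_features_invariant_to_appended_dead_samples(self, params):
        rng = np.random.default_rng(1)
        gyro = rng.normal(0, 150, (200, 3))
        acc_x = rng.normal(0, 1.0, 200)
        # appended samples: centre-region acceleration, zero rotation
        gyro_ext = np.vstack([gyro, np.zeros((50, 3))])
        acc_ext = np.concatenate([acc_x, np.zeros(50)])
        assert walking_gyro_energy(gyro_ext, params) == walking_gyro_energy(gyro, params)
        assert xy_gyro_correlation(gyro_ext, params) == xy_gyro_correlation(gyro, params)
        assert extension_flexion_diff(acc_ext, gyro_ext[:, 2], params) == (
            extension_flexion_diff(acc_x, gyro[:, 2], params)
        )
        assert region_sequence(acc_ext, 0.25).tolist()[: len(region_sequence(acc_x, 0.25))] == region_sequence(acc_x, 0.25).tolist()
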