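import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edaffect.errors import ValidationError
from edaffect.features import (
    FEATURE_NAMES,
    GSREvent,
    detect_gsr_events,
    extract_feature_matrix,
    gsr_features,
    statistical_features,
)
from edaffect.preprocessing import Segment, decompose_tonic_phasic

from .oracles import brute_gsr_scan


class TestDetectGsr:
    def test_single_event_example(self):
        events = detect_gsr_events(np.array([0, 0.5, 2.0, 1.0, 0.2]), fs=4.0)
        assert len(events) == 1
        (ev,) = events
        assert ev.trigger_index == 1  # derivative [0.5, 1.5, -1.0, -0.8]
        assert ev.peak_index == 2
        assert ev.amplitude == pytest.approx(2.0)
        assert ev.significant  # 2.0 > 1.5 µS

    def test_monotone_decreasing_has_no_events(self):
        assert detect_gsr_events(np.linspace(3, 0, 10), fs=4.0) == []

    def test_two_subthreshold_bumps(self):
        bump = [0.0, 0.2, 0.7, 1.0, 0.7, 0.2]
        x = np.array(bump + bump + [0.0])
        events = detect_gsr_events(x, fs=4.0)
        assert len(events) == 2
        assert all(ev.amplitude == pytest.approx(1.0) for ev in events)
        assert not any(ev.significant for ev in events)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            detect_gsr_events(np.array([0.0, 1.0]), fs=4.0)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-3, 3, allow_nan=False, width=32), min_size=3,
                    max_size=50))
    def test_agrees_with_brute_force_scan(self, values):
        phasic = np.asarray(values, dtype=float)
        got = detect_gsr_events(phasic, fs=4.0, min_amplitude=0.0)
        expected = brute_gsr_scan(phasic)
        assert [(e.trigger_index, e.peak_index) for e in got] == \
            [(t, p) for t, p, _, _ in expected]
        for e, (_, _, amp, sig) in zip(got, expected):
            assert e.amplitude == pytest.approx(amp)
            assert e.significant == sig

    def test_event_invariants(self):
        with pytest.raises(ValidationError):
            GSREvent(5, 3, 1.0, 1.0, False)
        with pytest.raises(ValidationError):
            GSREvent(1, 2, -0.5, 0.25, False)


class TestGsrFeatures:
    def test_single_event_arithmetic(self):
        ev = GSREvent(0, 1, 2.0, 4.0, True)
        out = gsr_features([ev], duration=10.0)
        assert out == {"n_gsr": 1.0, "rpm": 6.0, "gsr_energy": 4.0,
                       "n_sig_gsr": 1.0, "sig_gsr_energy": 4.0}

    def test_no_events_all_zero(self):
        out = gsr_features([], duration=10.0)
        assert set(out.values()) == {0.0}

    def test_rpm_scale(self):
        events = [GSREvent(i, i + 1, 0.5, 0.25, False) for i in range(0, 50, 10)]
        assert gsr_features(events, duration=60.0)["rpm"] == pytest.approx(5.0)

    def test_bad_duration_rejected(self):
        with pytest.raises(ValidationError):
            gsr_features([], duration=0.0)


class TestStatisticalFeatures:
    def test_linear_ramp_values(self):
        out = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out["mean"] == pytest.approx(2.5)
        assert out["p25"] == pytest.approx(1.75)
        assert out["p75"] == pytest.approx(3.25)
        assert out["quartile_deviation"] == pytest.approx(0.75)
        assert out["reg_slope"] == pytest.approx(1.0)
        assert out["reg_rmse"] == pytest.approx(0.0, abs=1e-9)
        assert out["n_crossings"] == 0
        assert out["total_sum"] == pytest.approx(10.0)
        assert out["rms"] == pytest.approx(np.sqrt(7.5))
        assert out["moment5"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_segment_conventions(self):
        out = statistical_features(np.full(8, 5.0))
        for key in ("variance", "entropy", "skewness", "kurtosis", "reg_slope"):
            assert out[key] == pytest.approx(0.0, abs=1e-9)

    def test_two_level_signal_has_one_bit_entropy(self):
        x = np.array([1.0] * 8 + [2.0] * 8)
        assert statistical_features(x)["entropy"] == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            statistical_features(np.array([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scaling_covariance(self, seed):
        """Scaling samples by c scales location/scale features by c, variance
        by c², and leaves shape features unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 5, 60)
        c = 2.5
        a, b = statistical_features(x), statistical_features(c * x)
        for key in ("mean", "standard_deviation", "median", "minimum",
                    "maximum", "total_sum", "p25", "p75", "quartile_deviation"):
            assert b[key] == pytest.approx(c * a[key])
        assert b["variance"] == pytest.approx(c**2 * a["variance"])
        assert b["skewness"] == pytest.approx(a["skewness"])
        assert b["n_crossings"] == a["n_crossings"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_quartile_and_order_invariants(self, seed):
        rng = np.random.default_rng(seed)
        out = statistical_features(rng.normal(4, 1, 50))
        assert out["quartile_deviation"] == pytest.approx(
            (out["p75"] - out["p25"]) / 2
        )
        assert out["minimum"] <= out["median"] <= out["maximum"]

    def test_gsr_amplitudes_scale_with_signal(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 0.2, 40))
        base = detect_gsr_events(x, fs=4.0)
        scaled = detect_gsr_events(3.0 * x, fs=4.0)
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert b.amplitude == pytest.approx(3.0 * a.amplitude)


class TestFeatureMatrix:
    def _tuple(self, pid, exercise_id=3):
        rng = np.random.default_rng(hash(pid) % 2**31)
        seg = Segment(pid, exercise_id, 4.0, rng.uniform(2, 6, 40))
        tp = decompose_tonic_phasic(seg)
        events = detect_gsr_events(tp.phasic, 4.0)
        return seg, tp, events

    def test_shape_and_column_order(self):
        fm = extract_feature_matrix([self._tuple("P001"), self._tuple("P002")])
        assert fm.data.shape == (2, 26)
        assert tuple(fm.feature_names) == FEATURE_NAMES
        assert fm.exercise_id == 3

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            extract_feature_matrix([])

    def test_duplicate_participant_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            extract_feature_matrix([self._tuple("P001"), self._tuple("P001")])

    def test_mixed_exercises_rejected(self):
        with pytest.raises(ValidationError, match="mixed"):
            extract_feature_matrix(
                [self._tuple("P001", 1), self._tuple("P002", 2)]
            )

    def test_synthetic_cohort_has_41_rows(self, cohort):
        from edaffect.pipeline import compute_features

        matrices = compute_features(cohort.sessions)
        assert set(matrices) == {1, 2, 3}
        assert all(m.data.shape == (41, 26) for m in matrices.values())

    def test_csv_round_trip(self, tmp_path):
        fm = extract_feature_matrix([self._tuple("P001"), self._tuple("P002")])
        fm.to_csv(tmp_path / "fm.csv")
        from edaffect.features import FeatureMatrix

        back = FeatureMatrix.from_csv(tmp_path / "fm.csv", exercise_id=3)
        np.testing.assert_allclose(back.values(), fm.values())
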