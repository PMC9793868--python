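"""Preprocessing chain: ΔF/F, event counting, high-pass, z-score, binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmfreact import (EventDetectionConfig, FluorescenceMatrix, PreprocessError,
                      TraceMatrix, bin_traces, compute_dff, detect_events,
                      highpass_filter, zscore_rectify)


def _raw(values, fr=20.0):
    return FluorescenceMatrix(np.asarray(values, dtype=float), frame_rate=fr)


class TestComputeDff:
    def test_constant_trace_maps_to_zero(self):
        out = compute_dff(_raw(np.full((50, 3), 5.0)))
        assert out.stage == "dff"
        np.testing.assert_allclose(out.values, 0.0)

    def test_two_frame_example(self):
        # F = [8, 12] → F0 = 10 → ΔF/F = [−0.2, +0.2]
        out = compute_dff(_raw([[8.0], [12.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-0.2, 0.2])

    def test_matches_elementwise_oracle(self, rng):
        f = rng.uniform(0.5, 2.0, (100, 5))
        out = compute_dff(_raw(f))
        oracle = (f - f.mean(axis=0)) / f.mean(axis=0)  # two-line oracle
        np.testing.assert_allclose(out.values, oracle)

    def test_zero_f0_names_neuron(self):
        f = np.ones((10, 3))
        f[:, 1] = 0.0
        with pytest.raises(PreprocessError, match="neuron id.*1"):
            compute_dff(_raw(f))

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale):
        """ΔF/F is invariant to positive rescaling of a neuron's raw trace."""
        rng = np.random.default_rng(0)
        f = rng.uniform(1.0, 2.0, (60, 2))
        base = compute_dff(_raw(f)).values
        f2 = f.copy()
        f2[:, 0] *= scale
        np.testing.assert_allclose(compute_dff(_raw(f2)).values, base, atol=1e-10)


class TestDetectEvents:
    def _dff(self, values):
        return TraceMatrix(np.asarray(values, dtype=float), stage="dff")

    def test_all_zero_trace_has_no_events(self):
        out = detect_events(self._dff(np.zeros((100, 2))))
        assert out.per_neuron.tolist() == [0, 0]
        assert out.per_session_mean == 0.0

    def test_planted_transients_counted_exactly(self):
        # 4 well-separated transients above both thresholds on low noise
        tr = np.zeros((400, 1))
        for t in (50, 150, 250, 350):
            tr[t:t + 8, 0] = np.linspace(1.0, 0.1, 8)
        out = detect_events(self._dff(tr))
        assert out.per_neuron[0] == 4

    def test_subthreshold_amplitude_rejected(self):
        # 0.005 a.u. transient fails the absolute 0.01 a.u. condition
        tr = np.zeros((200, 1))
        tr[100:105, 0] = 0.005
        out = detect_events(self._dff(tr), EventDetectionConfig(sd_multiplier=0.001))
        assert out.per_neuron[0] == 0

    def test_burst_counts_once(self):
        tr = np.zeros((100, 1))
        tr[40:50, 0] = [1.0, 0.2, 1.0, 0.2, 1.0, 0.2, 1.0, 0.2, 1.0, 0.2]
        out = detect_events(self._dff(tr), EventDetectionConfig(refractory_frames=10))
        assert out.per_neuron[0] == 1

    def test_monotone_in_sd_multiplier(self, rng):
        tr = self._dff(np.abs(rng.standard_normal((500, 4))))
        counts = [detect_events(tr, EventDetectionConfig(sd_multiplier=m)).per_neuron
                  for m in (1.0, 2.0, 3.0, 5.0)]
        for lo, hi in zip(counts[1:], counts[:-1]):
            assert np.all(lo <= hi)

    def test_requires_dff_stage(self):
        tr = TraceMatrix(np.zeros((10, 1)), stage="highpassed")
        with pytest.raises(PreprocessError, match="F/F"):
            detect_events(tr)


class TestHighpassFilter:
    def test_dc_rejection(self):
        tr = TraceMatrix(np.full((2000, 2), 3.0), stage="dff")
        out = highpass_filter(tr)
        assert out.stage == "highpassed"
        assert np.abs(out.values).max() < 1e-6 * 3.0

    def test_slow_drift_attenuated(self):
        # 0.001 Hz sinusoid, one decade below the 0.01 Hz cutoff
        fs, dur = 20.0, 2000.0
        t = np.arange(int(fs * dur)) / fs
        tr = TraceMatrix(np.sin(2 * np.pi * 0.001 * t)[:, None], stage="dff", frame_rate=fs)
        out = highpass_filter(tr).values[:, 0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(out[mid]).max() < 0.1  # > 90 % attenuation

    def test_passband_preserved(self):
        fs = 20.0
        t = np.arange(int(fs * 600)) / fs
        tr = TraceMatrix(np.sin(2 * np.pi * 1.0 * t)[:, None], stage="dff", frame_rate=fs)
        out = highpass_filter(tr).values[:, 0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert abs(np.abs(out[mid]).max() - 1.0) < 0.05

    def test_short_session_warns_but_filters(self):
        tr = TraceMatrix(np.random.default_rng(0).normal(size=(100, 1)), stage="dff")
        with pytest.warns(UserWarning, match="time constants"):
            out = highpass_filter(tr)
        assert out.values.shape == (100, 1)


class TestZscoreRectify:
    def _hp(self, values):
        return TraceMatrix(np.asarray(values, dtype=float), stage="highpassed")

    def test_symmetric_example(self):
        out = zscore_rectify(self._hp([[-1.0], [1.0], [-1.0], [1.0]]))
        assert out.stage == "zscored_rectified"
        np.testing.assert_allclose(out.values[:, 0], [0, 1, 0, 1])

    def test_matches_elementwise_oracle(self, rng):
        x = rng.standard_normal((200, 6))
        out = zscore_rectify(self._hp(x))
        oracle = np.clip((x - x.mean(0)) / x.std(0), 0, None)
        np.testing.assert_allclose(out.values, oracle)

    def test_zero_sd_column_zeroed(self):
        x = np.ones((50, 2))
        x[:, 1] = np.random.default_rng(1).standard_normal(50)
        out = zscore_rectify(self._hp(x))
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert out.values[:, 1].max() > 0

    def test_output_nonnegative(self, rng):
        out = zscore_rectify(self._hp(rng.standard_normal((300, 5))))
        assert np.all(out.values >= 0)


class TestBinTraces:
    def _z(self, values, fr=20.0):
        return TraceMatrix(np.asarray(values, dtype=float), stage="zscored_rectified",
                           frame_rate=fr)

    def test_bin_duration_200ms_at_20hz(self):
        out = bin_traces(self._z(np.zeros((40, 2))), bin_frames=4)
        assert out.bin_duration == pytest.approx(0.200)

    def test_constant_input_preserved(self):
        out = bin_traces(self._z(np.full((16, 3), 2.5)))
        np.testing.assert_allclose(out.values, 2.5)

    def test_trailing_partial_bin_dropped(self):
        out = bin_traces(self._z(np.ones((9, 1))), bin_frames=4)
        assert out.n_bins == 2

    def test_mean_vs_sum(self, rng):
        x = np.abs(rng.standard_normal((20, 3)))
        z = self._z(x)
        np.testing.assert_allclose(bin_traces(z, agg="sum").values,
                                   4 * bin_traces(z, agg="mean").values)

    def test_too_few_frames_errors(self):
        with pytest.raises(PreprocessError, match="bin"):
            bin_traces(self._z(np.ones((3, 1))), bin_frames=4)

    @given(n=st.integers(4, 200), bf=st.integers(1, 7))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bin_count_is_floor_division(self, n, bf):
        if n < bf:
            return
        out = bin_traces(self._z(np.ones((n, 2))), bin_frames=bf)
        assert out.n_bins == n // bf


def test_shape_conserved_through_pointwise_stages(rng):
    raw = FluorescenceMatrix(rng.uniform(0.5, 2.0, (1200, 7)))
    dff = compute_dff(raw)
    hp = highpass_filter(dff)
    z = zscore_rectify(hp)
    assert dff.values.shape == hp.values.shape == z.values.shape == (1200, 7)
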