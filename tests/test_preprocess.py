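import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apneakit as ak
from apneakit.preprocess import DegenerateSegmentWarning

# coefficients of the published difference equation, printed to 4 decimals
PRINTED_B = [0.1242, 0.0, -0.2483, 0.0, 0.1242]
PRINTED_A = [1.0, -2.7422, 2.7907, -1.3311, 0.2831]


def iterate_recurrence(b, a, x):
    """Direct simulation of the difference equation (independent oracle)."""
    y = np.zeros(len(x))
    for n in range(len(x)):
        acc = sum(b[k] * x[n - k] for k in range(len(b)) if n - k >= 0)
        acc -= sum(a[k] * y[n - k] for k in range(1, len(a)) if n - k >= 0)
        y[n] = acc
    return y


class TestDesignBandpass:
    def test_printed_coefficients_reproduced(self, default_filter):
        b, a = np.asarray(default_filter.b), np.asarray(default_filter.a)
        assert round(b[0], 4) == 0.1242
        assert np.allclose(np.round(b, 4), PRINTED_B)
        assert np.allclose(np.round(a, 4), PRINTED_A)

    def test_numerator_structure(self, default_filter):
        b = np.asarray(default_filter.b)
        assert np.allclose(b / b[0], [1, 0, -2, 0, 1], atol=1e-10)

    @pytest.mark.parametrize("band", [(0.5, 15.0), (1.0, 20.0), (2.0, 30.0)])
    def test_zero_gain_at_dc_and_nyquist(self, band):
        c = ak.design_bandpass(100.0, *band)
        assert abs(c.response_at(0.0)) < 1e-6
        assert abs(c.response_at(50.0)) < 1e-6

    @pytest.mark.parametrize("low,high", [(0, 15), (15, 0.5), (0.5, 60),
                                          (-1, 15)])
    def test_invalid_band_edges_rejected(self, low, high):
        with pytest.raises(ValueError):
            ak.design_bandpass(100.0, low, high)

    def test_impulse_response_equals_recurrence_simulation(self,
                                                           default_filter):
        x = np.zeros(100)
        x[0] = 1.0
        y = ak.apply_filter(x, default_filter)
        oracle = iterate_recurrence(default_filter.b, default_filter.a, x)
        assert np.max(np.abs(y - oracle)) < 1e-12

    def test_design_close_to_printed_recurrence(self, default_filter):
        # the published coefficients are rounded to 4 decimals; iterating
        # them diverges slowly from the exact design (poles near |z|=1)
        x = np.zeros(100)
        x[0] = 1.0
        y = ak.apply_filter(x, default_filter)
        printed = iterate_recurrence(PRINTED_B, PRINTED_A, x)
        assert np.max(np.abs(y - printed)) < 5e-3


class TestApplyFilter:
    def test_zero_input_gives_zero_output(self, default_filter):
        assert np.all(ak.apply_filter(np.zeros(50), default_filter) == 0)

    def test_impulse_first_sample_is_b0(self, default_filter):
        x = np.zeros(10)
        x[0] = 1.0
        y = ak.apply_filter(x, default_filter)
        assert y[0] == pytest.approx(default_filter.b[0])

    def test_baseline_wander_attenuated_over_20db(self, default_filter):
        # steady-state gain ratio between a 0.05 Hz drift and a 2 Hz tone
        g_low = abs(default_filter.response_at(0.05))
        g_band = abs(default_filter.response_at(2.0))
        assert 20 * np.log10(g_band / g_low) > 20.0

    @given(alpha=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, alpha):
        c = ak.design_bandpass(100.0, 0.5, 15.0)
        x = np.sin(np.arange(200) / 7.0)
        lhs = ak.apply_filter(alpha * x, c)
        rhs = alpha * ak.apply_filter(x, c)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_output_length_matches_input(self, default_filter):
        for n in (1, 5, 6000):
            assert len(ak.apply_filter(np.ones(n), default_filter)) == n


class TestZscore:
    def test_definition_on_three_points(self):
        z = ak.zscore([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(z, [-np.sqrt(1.5), 0, np.sqrt(1.5)])

    def test_constant_sequence_returns_zeros_with_warning(self):
        with pytest.warns(DegenerateSegmentWarning):
            z = ak.zscore(np.full(100, 3.7))
        assert np.all(z == 0)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_idempotence(self, seed):
        x = np.random.default_rng(seed).standard_normal(500)
        once = ak.zscore(x)
        twice = ak.zscore(once)
        assert np.allclose(once, twice, atol=1e-9)

    def test_population_sd_convention(self):
        x = np.array([0.0, 1.0])
        # population sd of [0,1] is 0.5, so z = [-1, 1]
        assert np.allclose(ak.zscore(x), [-1.0, 1.0])


class TestPreprocessRecording:
    def test_segment_count_shape_and_moments(self, small_cohort):
        _, records, _ = small_cohort
        rec = records[0]
        segs = ak.preprocess_recording(rec)
        assert len(segs) == rec.n_minutes
        for s in segs:
            assert len(s.values) == 6000
            assert abs(s.values.mean()) < 1e-9
            assert abs(s.values.std() - 1.0) < 1e-6
            assert s.label in ("N", "A")

    def test_labels_carried_through(self, small_cohort):
        _, records, _ = small_cohort
        rec = records[0]
        segs = ak.preprocess_recording(rec)
        assert [s.label for s in segs] == rec.minute_labels

    def test_drift_amplitude_reduced_after_filtering(self, default_filter):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        beats = np.zeros_like(t)
        beats[::85] = 1.0
        drift = 5.0 * np.sin(2 * np.pi * 0.1 * t)
        raw = beats + drift
        filtered = ak.apply_filter(raw, default_filter)
        steady = filtered[int(10 * fs):]  # past the onset transient
        assert np.ptp(steady) < 0.5 * np.ptp(raw)

    def test_minutes_processed_independently(self, small_cohort):
        _, records, _ = small_cohort
        rec = records[2]
        segs = ak.preprocess_recording(rec)
        # re-preprocess a single minute in isolation: identical output
        sub = ak.ECGRecording("sub", rec.fs, rec.minute(3),
                              [rec.minute_labels[3]])
        alone = ak.preprocess_recording(sub)[0]
        assert np.allclose(alone.values, segs[3].values)
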