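import numpy as np
import pytest

from seizurepath import SeizureRecording
from seizurepath.preprocess import (
    common_average_reference,
    detect_dropout_windows,
    filter_recording,
    interpolate_short_gaps,
    line_length,
    resample_to_common,
)


def _rec(data, fs=100.0, **kw):
    return SeizureRecording(data=np.asarray(data, float), fs=fs, **kw)


class TestLineLength:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([3.0, 3.0, 3.0, 3.0], 0.0),
            ([0.0, 1.0, 0.0, 1.0], 1.0),
            ([0.0, 2.0, 0.0], 2.0),
        ],
    )
    def test_examples(self, x, expected):
        assert line_length(np.array(x)) == pytest.approx(expected)

    def test_too_short(self):
        with pytest.raises(ValueError):
            line_length(np.array([1.0]))


class TestDropoutDetection:
    def test_all_zero_recording_fully_flagged(self):
        rec = _rec(np.zeros((16, 1000)))
        mask = detect_dropout_windows(rec)
        assert mask.all()

    def test_flat_on_half_montage_flags_with_neighbours(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(16, 2000)) * 10
        # flatten 8 of 16 channels over 0.5 s in the middle
        data[:8, 1000:1050] = 5.0
        rec = _rec(data)
        mask = detect_dropout_windows(rec)
        assert mask[:, 1000:1050].all()
        # neighbouring windows (0.05 s each side) are flagged too
        assert mask[:, 995:1000].all() and mask[:, 1050:1055].all()
        # far-away clean signal untouched
        assert not mask[:, :900].any() and not mask[:, 1200:].any()

    def test_flat_on_seven_of_sixteen_not_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(16, 2000)) * 10
        data[:7, 1000:1050] = 5.0
        rec = _rec(data)
        assert not detect_dropout_windows(rec).any()

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(10, 1500)) * 10
        data[2:8, 600:700] = 1.0
        perm = rng.permutation(10)
        m1 = detect_dropout_windows(_rec(data))
        m2 = detect_dropout_windows(_rec(data[perm]))
        # the flag set is a property of the window, not of channel order
        assert np.array_equal(m1.any(axis=0), m2.any(axis=0))


class TestInterpolation:
    def test_short_gap_filled_linearly(self):
        data = np.array([[0.0, 99.0, 99.0, 3.0, 4.0]])
        mask = np.array([[False, True, True, False, False]])
        rec = _rec(data, fs=100.0, missing_mask=mask)
        out = interpolate_short_gaps(rec, max_gap_s=0.05)
        np.testing.assert_allclose(out.data[0], [0.0, 1.0, 2.0, 3.0, 4.0])
        assert not out.missing_mask.any()

    def test_long_gap_untouched(self):
        data = np.array([[0.0, 99.0, 99.0, 99.0, 99.0, 99.0, 5.0]])
        mask = np.zeros_like(data, dtype=bool)
        mask[0, 1:6] = True
        rec = _rec(data, fs=100.0, missing_mask=mask)
        out = interpolate_short_gaps(rec, max_gap_s=0.05)  # gap = 0.05 s, not < max
        np.testing.assert_array_equal(out.data, data)
        assert out.missing_mask.sum() == 5

    def test_edge_gap_left_missing(self):
        data = np.array([[99.0, 1.0, 2.0]])
        mask = np.array([[True, False, False]])
        out = interpolate_short_gaps(_rec(data, missing_mask=mask), max_gap_s=0.05)
        assert out.missing_mask[0, 0]

    def test_no_gap_identity(self):
        data = np.random.default_rng(0).normal(size=(2, 50))
        out = interpolate_short_gaps(_rec(data))
        np.testing.assert_array_equal(out.data, data)


class TestCommonAverageReference:
    def test_zero_mean_after_car(self):
        rec = _rec(np.random.default_rng(1).normal(size=(5, 200)))
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_idempotent(self):
        rec = _rec(np.random.default_rng(2).normal(size=(5, 200)))
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_excluded_channels_left_alone(self):
        data = np.random.default_rng(3).normal(size=(4, 100))
        rec = _rec(data.copy(), excluded_channels={3})
        out = common_average_reference(rec)
        np.testing.assert_array_equal(out.data[3], data[3])
        np.testing.assert_allclose(out.data[:3].mean(axis=0), 0.0, atol=1e-9)

    def test_single_channel_error(self):
        with pytest.raises(ValueError):
            common_average_reference(_rec(np.zeros((1, 100))))


class TestFiltering:
    fs = 500.0

    def _sine(self, freq, dur=4.0):
        t = np.arange(int(dur * self.fs)) / self.fs
        return np.sin(2 * np.pi * freq * t)[None, :]

    def test_notch_attenuates_mains(self):
        rec = _rec(self._sine(50.0), fs=self.fs)
        out = filter_recording(rec, notch_freqs=(50.0,))
        mid = slice(500, 1500)  # avoid filtfilt edge transients
        p_in = (rec.data[0, mid] ** 2).mean()
        p_out = (out.data[0, mid] ** 2).mean()
        assert p_out < 0.01 * p_in

    def test_dc_removed(self):
        rec = _rec(np.full((1, 2000), 7.3), fs=self.fs)
        out = filter_recording(rec, notch_freqs=())
        assert abs(out.data[0, 500:1500].mean()) < 1e-3

    def test_passband_unity_gain(self):
        rec = _rec(self._sine(10.0), fs=self.fs)
        out = filter_recording(rec)
        mid = slice(500, 1500)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert 0.9 < ratio < 1.1

    def test_fs_too_low(self):
        with pytest.raises(ValueError):
            filter_recording(_rec(np.zeros((2, 100)), fs=250.0))


class TestResampling:
    def test_equal_fs_identity(self):
        recs = [_rec(np.random.default_rng(0).normal(size=(2, 100)), fs=100.0)]
        out = resample_to_common(recs)
        np.testing.assert_array_equal(out[0].data, recs[0].data)

    def test_halving_sample_count(self):
        recs = [
            _rec(np.zeros((2, 1000)), fs=1000.0),
            _rec(np.zeros((2, 500)), fs=500.0),
        ]
        out = resample_to_common(recs)
        assert out[0].fs == 500.0
        assert abs(out[0].n_samples - 500) <= 1

    def test_subnyquist_content_preserved(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        recs = [_rec(x, fs=fs), _rec(np.zeros((1, 2000)), fs=500.0)]
        out = resample_to_common(recs)
        rms_in = np.sqrt((x[0, 500:3500] ** 2).mean())
        y = out[0].data[0]
        rms_out = np.sqrt((y[250:1750] ** 2).mean())
        assert abs(rms_out - rms_in) / rms_in < 0.05
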