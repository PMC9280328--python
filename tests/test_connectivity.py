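import numpy as np
import pytest

from seizurepath import (
    CANONICAL_BANDS,
    SeizureRecording,
    band_coherence,
    compute_fc_series,
    exclude_incomplete_seizures,
)
from seizurepath.connectivity import coherence_matrices, n_fc_windows
from seizurepath.synthetic import inject_dropout


FS = 512.0


def _noise(seed, n_ch=2, dur=10.0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n_ch, int(dur * FS)))


class TestBandCoherence:
    def test_identical_signals_give_unit_coherence(self):
        x = _noise(0, 1)[0]
        for band in CANONICAL_BANDS.values():
            assert band_coherence(x, x, band, FS) == pytest.approx(1.0, abs=1e-9)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=(2, int(10 * FS)))
            for band in CANONICAL_BANDS.values():
                c = band_coherence(x, y, band, FS)
                assert 0.0 <= c <= 1.0

    def test_independent_noise_below_null_quantile(self):
        """White-noise pairs rarely exceed the simulated null 95th percentile."""
        null = np.array(
            [
                [
                    band_coherence(*_noise(1000 + r), band, FS)
                    for band in CANONICAL_BANDS.values()
                ]
                for r in range(500)
            ]
        )
        q95 = np.quantile(null, 0.95, axis=0)
        fresh = np.array(
            [
                [
                    band_coherence(*_noise(50_000 + r), band, FS)
                    for band in CANONICAL_BANDS.values()
                ]
                for r in range(200)
            ]
        )
        exceed = (fresh > q95).mean(axis=0)
        assert (exceed < 0.15).all()  # nominal 5% per band

    def test_small_delay_keeps_high_coherence(self):
        # constant lag much shorter than the 2 s Welch window barely rotates
        # in-band phases, so coherence in the driving band stays near 1
        rng = np.random.default_rng(2)
        from scipy import signal as sps

        src = sps.sosfiltfilt(
            sps.butter(4, (8, 13), btype="bandpass", fs=FS, output="sos"),
            rng.normal(size=int(12 * FS)),
        )
        lag = int(0.01 * FS)
        x = src[lag : lag + int(10 * FS)]
        y = src[: int(10 * FS)]
        assert band_coherence(x, y, (8, 13), FS) > 0.9

    def test_empty_band_rejected(self):
        x = _noise(3, 1, dur=10.0)[0]
        with pytest.raises(ValueError):
            band_coherence(x, x, (100.1, 100.3), FS)  # no FFT bin in between


class TestFcSeries:
    def test_window_count_rule(self):
        assert n_fc_windows(30.0) == 21
        assert n_fc_windows(10.0) == 1
        assert n_fc_windows(9.9) == 0

    def test_feature_count_and_band_normalization(self):
        rec = SeizureRecording(data=_noise(4, n_ch=4, dur=14.0), fs=FS)
        fc = compute_fc_series(rec)
        assert fc.features.shape == (5, 6 * 6)  # floor(14) - 9 windows
        for b in range(6):
            np.testing.assert_allclose(
                fc.features[:, fc.band_slice(b)].sum(axis=1), 1.0, atol=1e-9
            )
        assert (fc.features >= 0).all()

    def test_too_short_seizure_rejected(self):
        rec = SeizureRecording(data=_noise(5, n_ch=2, dur=8.0), fs=FS)
        with pytest.raises(ValueError):
            compute_fc_series(rec)

    def test_channel_permutation_permutes_features(self):
        data = _noise(6, n_ch=4, dur=12.0)
        fc1 = compute_fc_series(SeizureRecording(data=data, fs=FS))
        perm = np.array([2, 0, 3, 1])
        fc2 = compute_fc_series(SeizureRecording(data=data[perm], fs=FS))
        # map each permuted feature back through the band_index/pair maps:
        # channel a of fc2 is original channel perm[a]
        for j in range(fc2.features.shape[1]):
            i2, k2 = fc2.pair_of_feature(j)
            band = fc2.band_of_feature(j)
            orig = tuple(sorted((int(perm[i2]), int(perm[k2]))))
            iu = np.triu_indices(4, k=1)
            r = [
                q for q in range(6) if (int(iu[0][q]), int(iu[1][q])) == orig
            ][0]
            j1 = fc1.band_slice(band).start + r
            np.testing.assert_allclose(fc2.features[:, j], fc1.features[:, j1],
                                       atol=1e-9)

    def test_missing_subwindow_tolerance(self):
        """A window loses <5 subwindows -> computed; >=5 -> marked missing."""
        rec = SeizureRecording(data=_noise(7, n_ch=16, dur=15.0), fs=FS)
        # 0.2-4.3 s touches the first window's subwindows starting 0..4 s: 5
        dropped = inject_dropout(rec, [(0.2, 4.3)])
        fc = compute_fc_series(dropped)
        assert fc.missing_windows[0]
        # window 1 loses only subwindows 1..4 (4 < 5): computed from the rest
        assert not fc.missing_windows[1:].any()
        short = inject_dropout(rec, [(0.2, 1.0)])  # touches a single subwindow
        fc2 = compute_fc_series(short)
        assert not fc2.missing_windows.any()

    def test_exclude_incomplete(self):
        rec = SeizureRecording(data=_noise(8, n_ch=4, dur=12.0), fs=FS)
        good = compute_fc_series(rec)
        bad = good.sliced(slice(None))
        bad.missing_windows[1] = True
        kept, excluded = exclude_incomplete_seizures({"a": good, "b": bad})
        assert list(kept) == ["a"] and excluded == ["b"]
        kept2, excluded2 = exclude_incomplete_seizures({"a": good})
        assert list(kept2) == ["a"] and excluded2 == []


class TestRawSignalRoundTrip:
    def test_common_source_pair_high_alpha_coherence(self):
        rng = np.random.default_rng(9)
        from scipy import signal as sps

        src = sps.sosfiltfilt(
            sps.butter(4, (8, 13), btype="bandpass", fs=FS, output="sos"),
            rng.normal(size=int(10 * FS)),
        )
        X = np.vstack([src, src])
        C = coherence_matrices(X, FS, bands=[(8, 13)])
        assert C[0, 0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_state_recovery_by_nearest_template(self):
        """Windows of a raw 2-state seizure match their true state template."""
        from seizurepath import LatentPathway, SeizureSpec, make_dictionary
        from seizurepath.synthetic import realize_raw_seizure

        d = make_dictionary(n_channels=6, n_states=2, seed=0)
        pathway = LatentPathway([0, 1], [0.5, 0.5])
        spec = SeizureSpec(pathway_id=0, duration_s=40.0, noise_sd=0.05, seed=1)
        rec = realize_raw_seizure(d, pathway, spec, fs=FS)
        fc = compute_fc_series(rec)
        templates = np.array([d.flat(0), d.flat(1)])
        assigned = np.array(
            [
                np.abs(templates - w).sum(axis=1).argmin()
                for w in fc.features
            ]
        )
        truth = np.array(
            [pathway.state_sequence[int((w + 0.5) / fc.n_windows >= 0.5)]
             for w in range(fc.n_windows)]
        )
        agreement = (assigned == truth).mean()
        assert agreement > 0.8
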