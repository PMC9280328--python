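import numpy as np
import pytest

from seizurepath import (
    CohortConfig,
    DurationModel,
    LatentPathway,
    SeizureRecording,
    SeizureSpec,
    dtw_dissimilarity,
    generate_cohort,
    inject_dropout,
    make_dictionary,
    realize_fc_series,
)
from seizurepath.preprocess import detect_dropout_windows
from seizurepath.synthetic import _prefix_states
from seizurepath.truncation import pathway_size


class TestMakeDictionary:
    def test_band_blocks_normalised(self):
        d = make_dictionary(n_channels=4, n_states=1, seed=0)
        assert d.templates.shape == (1, 6, 6)
        np.testing.assert_allclose(d.templates.sum(axis=2), 1.0, atol=1e-12)

    def test_feature_length(self):
        d = make_dictionary(n_channels=16, n_states=5, seed=1)
        assert d.flat(0).size == 6 * 120

    def test_deterministic(self):
        d1 = make_dictionary(n_channels=8, n_states=4, seed=5)
        d2 = make_dictionary(n_channels=8, n_states=4, seed=5)
        np.testing.assert_array_equal(d1.templates, d2.templates)

    def test_states_mutually_distinguishable(self):
        from scipy.spatial.distance import pdist

        d = make_dictionary(n_channels=10, n_states=6, seed=2, margin=3.0)
        flats = np.array([d.flat(k) for k in range(6)])
        assert pdist(flats, metric="cityblock").min() > 3.0

    def test_impossible_margin_fails(self):
        with pytest.raises(RuntimeError):
            # total band mass is 6; pairwise cityblock can never exceed 12
            make_dictionary(n_channels=4, n_states=3, seed=0, margin=15.0,
                            max_retries=5)


class TestRealizeFcSeries:
    def setup_method(self):
        self.dict = make_dictionary(n_channels=6, n_states=3, seed=0)
        self.pathway = LatentPathway([0, 1, 2], [0.3, 0.4, 0.3])

    def test_window_count_rule(self):
        spec = SeizureSpec(pathway_id=0, duration_s=30.0, seed=0)
        fc = realize_fc_series(self.dict, self.pathway, spec)
        assert fc.n_windows == 21

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spec = SeizureSpec(pathway_id=0, duration_s=25.0,
                               truncate_fraction=0.3, seed=0)
            realize_fc_series(self.dict, self.pathway, spec)

    def test_elastic_pair_near_zero_dissimilarity(self):
        a = realize_fc_series(
            self.dict, self.pathway,
            SeizureSpec(pathway_id=0, duration_s=20.0, seed=0),
        )
        b = realize_fc_series(
            self.dict, self.pathway,
            SeizureSpec(pathway_id=0, duration_s=40.0, seed=1),
        )
        assert dtw_dissimilarity(a, b) < 0.3  # noiseless: only fade windows differ

    def test_truncation_keeps_leading_dwell_mass(self):
        pathway = LatentPathway(np.arange(3), [0.25, 0.25, 0.5])
        spec = SeizureSpec(pathway_id=0, duration_s=100.0,
                           truncate_fraction=0.4, seed=0)
        fc, states = realize_fc_series(self.dict, pathway, spec,
                                       return_states=True)
        prefix = set(_prefix_states(pathway, 0.4))
        assert set(states) <= prefix
        assert 2 not in states  # the final state starts at dwell mass 0.5

    def test_truncated_child_smaller_and_shorter(self):
        # the generator orders truncation pathways so the prefix spread is
        # strictly below the full spread; realized sizes must follow suit
        from seizurepath.synthetic import _sound_truncation_pathway

        rng = np.random.default_rng(0)
        pathway = _sound_truncation_pathway(self.dict, np.arange(3), 0.4, rng)
        parent_spec = SeizureSpec(pathway_id=0, duration_s=80.0, seed=0)
        child_spec = SeizureSpec(pathway_id=0, duration_s=80.0,
                                 truncate_fraction=0.4, seed=1)
        parent = realize_fc_series(self.dict, pathway, parent_spec)
        child = realize_fc_series(self.dict, pathway, child_spec)
        assert child_spec.effective_duration_s < parent_spec.effective_duration_s
        assert pathway_size(child) < pathway_size(parent)

    def test_noise_keeps_band_normalisation(self):
        spec = SeizureSpec(pathway_id=0, duration_s=30.0, noise_sd=1e-3, seed=3)
        fc = realize_fc_series(self.dict, self.pathway, spec)
        assert (fc.features >= 0).all()
        for b in range(6):
            np.testing.assert_allclose(
                fc.features[:, fc.band_slice(b)].sum(axis=1), 1.0, atol=1e-9
            )

    def test_deterministic(self):
        spec = SeizureSpec(pathway_id=0, duration_s=30.0, noise_sd=1e-3, seed=4)
        f1 = realize_fc_series(self.dict, self.pathway, spec)
        f2 = realize_fc_series(self.dict, self.pathway, spec)
        np.testing.assert_array_equal(f1.features, f2.features)


class TestGenerateCohort:
    def test_pair_counts(self):
        cfg = CohortConfig(n_pathways=2, seizures_per_pathway=5,
                           n_elastic_pairs=0, n_semblant_pairs=0,
                           n_truncation_pairs=0)
        c = generate_cohort(cfg, seed=0)
        assert c.n_seizures == 10
        labels = c.pair_labels[np.triu_indices(10, k=1)]
        assert labels.size == 45
        assert (labels == "unrelated").sum() == 25
        assert (labels == "same-pathway").sum() == 20

    def test_requested_truncation_pairs_exact(self):
        cfg = CohortConfig(n_truncation_pairs=4)
        c = generate_cohort(cfg, seed=1)
        assert len(c.pairs_with_label("truncated")) == 4

    def test_inconsistent_request_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_pathways=1, n_semblant_pairs=1), seed=0)

    def test_bimodal_log_durations_separate(self):
        cfg = CohortConfig(
            n_pathways=2, seizures_per_pathway=30,
            n_elastic_pairs=0, n_semblant_pairs=0, n_truncation_pairs=0,
            duration_model=DurationModel(bimodal=True),
        )
        c = generate_cohort(cfg, seed=2)
        logd = np.sort(np.log(c.durations_array()))
        # dip-style check: the largest gap between consecutive sorted log
        # durations dwarfs the median gap (two well-separated modes)
        gaps = np.diff(logd)
        assert gaps.max() > 5 * np.median(gaps)

    def test_deterministic_from_seed(self):
        cfg = CohortConfig()
        c1 = generate_cohort(cfg, seed=9)
        c2 = generate_cohort(cfg, seed=9)
        assert c1.durations_s == c2.durations_s
        for sid in c1.seizure_ids:
            np.testing.assert_array_equal(c1.fc[sid].features, c2.fc[sid].features)
        np.testing.assert_array_equal(c1.pair_labels, c2.pair_labels)

    def test_noiseless_within_below_between(self):
        for seed in range(3):
            cfg = CohortConfig(noise_sd=0.0, seizures_per_pathway=3,
                               n_elastic_pairs=1, n_semblant_pairs=1,
                               n_truncation_pairs=0)
            c = generate_cohort(cfg, seed=seed)
            from seizurepath import pathway_dissimilarity_matrix

            D = pathway_dissimilarity_matrix(c.fc).values
            within = [D[i, j] for lab in ("same-pathway", "elastic")
                      for i, j in c.pairs_with_label(lab)]
            between = [D[i, j] for lab in ("unrelated", "semblant")
                       for i, j in c.pairs_with_label(lab)]
            assert max(within) < min(between)


class TestInjectDropout:
    def _rec(self, seed=0):
        rng = np.random.default_rng(seed)
        return SeizureRecording(data=rng.normal(size=(16, 2000)) * 10, fs=100.0)

    def test_round_trip_with_detector(self):
        rec = inject_dropout(self._rec(), [(5.0, 5.5)])
        mask = detect_dropout_windows(rec)
        assert mask[:, 510:540].all()

    def test_empty_spec_identity(self):
        rec = self._rec()
        out = inject_dropout(rec, [])
        np.testing.assert_array_equal(out.data, rec.data)
        assert not out.missing_mask.any()

    def test_partial_montage_not_flagged(self):
        rec = inject_dropout(self._rec(), [(5.0, 5.5, list(range(7)))])
        assert not detect_dropout_windows(rec).any()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            inject_dropout(self._rec(), [(1.0, 2.0), (1.5, 2.5)])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inject_dropout(self._rec(), [(19.0, 21.0)])
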