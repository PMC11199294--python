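import numpy as np
import pytest

from midstates.microstates import (
    MicrostateModel,
    Segmentation,
    appearance_windows,
    backfit,
    cross_validate_k,
    explained_variance,
    extract_features,
    fit_microstates,
    match_templates,
)


def orthonormal_maps(k, n_ch, rng):
    raw = rng.normal(size=(n_ch, k))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    maps = q.T  # rows orthonormal
    maps -= maps.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


class TestFit:
    def test_recovers_planted_orthogonal_templates(self, rng):
        planted = orthonormal_maps(4, 12, rng)
        # noise-free alternation with varying positive amplitudes
        maps = np.concatenate(
            [a * planted for a in (1.0, 2.0, 0.5, 3.0, 1.5)], axis=0
        )
        model = fit_microstates(maps, 4, n_restarts=10, seed=0)
        aligned = match_templates(model, planted)
        cos = np.abs(np.sum(aligned.templates * planted, axis=1))
        assert np.all(cos > 0.999)
        assert explained_variance(model, maps) == pytest.approx(1.0, abs=1e-9)

    def test_k1_on_scaled_single_map(self, rng):
        u = orthonormal_maps(1, 8, rng)[0]
        maps = np.stack([a * u for a in (0.5, 1.0, 2.0, 4.0)])
        model = fit_microstates(maps, 1, n_restarts=3, seed=0)
        assert abs(model.templates[0] @ u) > 1 - 1e-9
        assert model.train_explained_variance == pytest.approx(1.0, abs=1e-12)

    def test_train_ev_nondecreasing_in_k(self, rng):
        maps = rng.normal(size=(60, 10))
        maps -= maps.mean(axis=1, keepdims=True)
        evs = [
            fit_microstates(maps, k, n_restarts=10, seed=5).train_explained_variance
            for k in (1, 2, 3, 4)
        ]
        assert all(b >= a - 1e-6 for a, b in zip(evs, evs[1:]))

    def test_k_exceeding_channel_rank_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_microstates(rng.normal(size=(20, 5)), 5, seed=0)

    def test_full_rank_k_explains_everything(self, rng):
        # with k = channels - 1 templates on noise-free full-rank data the
        # assigned projections recover all topographic variance
        planted = orthonormal_maps(7, 8, rng)
        maps = np.concatenate([planted, 2 * planted], axis=0)
        model = fit_microstates(maps, 7, n_restarts=20, seed=1)
        assert explained_variance(model, maps) == pytest.approx(1.0, abs=1e-6)


class TestExplainedVariance:
    def test_bounds(self, rng):
        basis = orthonormal_maps(4, 8, rng)
        u, v = basis[:2], basis[2:]
        model = MicrostateModel(u)
        assert explained_variance(model, np.stack([3 * u[0], 2 * u[1]])) == (
            pytest.approx(1.0)
        )
        # polarity-sensitive models treat a negated template as a different
        # state: the flipped map is not assigned to its source template
        assert explained_variance(model, np.stack([3 * u[0], -2 * u[1]])) < 1.0
        insensitive = MicrostateModel(u, polarity_sensitive=False)
        assert explained_variance(
            insensitive, np.stack([3 * u[0], -2 * u[1]])
        ) == pytest.approx(1.0)
        # maps orthogonal to every template explain almost nothing
        assert explained_variance(model, 5 * v) < 1e-12

    def test_matches_brute_force_projection_sum(self, rng):
        templates = orthonormal_maps(3, 9, rng)
        model = MicrostateModel(templates)
        maps = rng.normal(size=(20, 9))
        maps -= maps.mean(axis=1, keepdims=True)
        proj = maps @ templates.T
        best = np.max(proj, axis=1) ** 2  # polarity-sensitive assignment
        expected = best.sum() / np.sum(maps**2)
        assert explained_variance(model, maps) == pytest.approx(expected, abs=1e-12)


class TestBackfit:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.templates = orthonormal_maps(3, 10, rng)
        self.model = MicrostateModel(self.templates)
        self.times = np.arange(0.0, 100.0, 10.0)

    def test_template_map_gets_its_label_and_gfp_squared_ev(self):
        erp = np.tile(2.0 * self.templates[1][:, None], (1, 10))
        seg = backfit(self.model, erp, self.times)
        assert np.all(seg.labels == 2)
        # collinear map: explained variance per sample equals gfp^2
        np.testing.assert_allclose(seg.ev_curve, seg.gfp_curve**2, atol=1e-12)

    def test_orthogonal_map_ties_to_lowest_class(self):
        # disjoint-support bipolar maps give exactly-zero projections, so
        # the tie rule (lowest class index) is exercised without float fuzz
        s = 1 / np.sqrt(2)
        templates = np.zeros((3, 10))
        templates[0, :2] = (s, -s)
        templates[1, 2:4] = (s, -s)
        templates[2, 4:6] = (s, -s)
        v = np.zeros(10)
        v[6:8] = (1.0, -1.0)
        erp = np.tile(v[:, None], (1, 10))
        seg = backfit(MicrostateModel(templates, polarity_sensitive=False),
                      erp, self.times)
        np.testing.assert_allclose(seg.ev_curve, 0.0, atol=1e-15)
        assert np.all(seg.labels == 1)

    def test_labels_invariant_to_positive_rescaling(self, rng):
        erp = rng.normal(size=(10, 10))
        seg1 = backfit(self.model, erp, self.times)
        seg2 = backfit(self.model, 17.0 * erp, self.times)
        np.testing.assert_array_equal(seg1.labels, seg2.labels)

    def test_window_outside_data_rejected(self):
        erp = np.zeros((10, 10))
        # times span 0-90 ms; a disjoint window has no samples to fit
        with pytest.raises(ValueError):
            backfit(self.model, erp, self.times, window=(200.0, 500.0))


class TestFeatures:
    def _segmentation(self, labels, ev, fs=1000.0):
        labels = np.asarray(labels)
        times = np.arange(len(labels)) * 1000.0 / fs
        gfp_curve = np.sqrt(np.asarray(ev, float))
        return Segmentation(labels, np.asarray(ev, float), gfp_curve, times,
                            int(labels.max()))

    def test_onset_offset_duration_at_1khz(self):
        labels = np.ones(30, int)
        labels[10:21] = 2
        seg = self._segmentation(labels, np.ones(30))
        f = extract_features(seg, 2)
        assert (f.onset, f.offset, f.duration) == (10.0, 20.0, 10.0)

    def test_uniform_ev_centers_cog(self):
        labels = np.ones(301, int)
        labels[100:201] = 2
        seg = self._segmentation(labels, np.ones(301))
        f = extract_features(seg, 2)
        assert f.cog == pytest.approx(150.0)

    def test_auc_closed_form(self):
        # ev = 0.5 µV² over a 100 ms span at 1 kHz -> auc = 0.5 * 101 samples
        labels = np.ones(301, int)
        labels[100:201] = 2
        seg = self._segmentation(labels, np.full(301, 0.5))
        f = extract_features(seg, 2)
        assert f.auc == pytest.approx(0.5 * 101 * 1.0)

    def test_cog_between_onset_and_offset(self, rng):
        labels = rng.integers(1, 4, size=60)
        ev = rng.uniform(0.1, 2.0, size=60)
        seg = self._segmentation(labels, ev)
        for class_id in (1, 2, 3):
            f = extract_features(seg, class_id, check_contiguous=False)
            if f is not None:
                assert f.onset <= f.cog <= f.offset
                assert f.duration == f.offset - f.onset

    def test_absent_class_returns_none(self):
        seg = self._segmentation(np.ones(20, int), np.ones(20))
        assert extract_features(seg, 1, analysis_window=(0.0, 19.0)) is not None
        seg2 = self._segmentation(np.full(20, 2, int), np.ones(20))
        assert extract_features(seg2, 1) is None

    def test_appearance_windows_split_runs(self):
        labels = np.array([1, 1, 2, 2, 1, 1, 1, 2, 2, 2])
        seg = self._segmentation(labels, np.ones(10))
        assert appearance_windows(seg, 2) == [(2.0, 3.0), (7.0, 9.0)]


class TestCrossValidation:
    def test_single_k_curve(self, rng):
        maps = rng.normal(size=(40, 8))

        def builder(subjects):
            return maps

        curve = cross_validate_k(builder, list("abcdefgh"), [2], n_splits=2, seed=0)
        assert curve.selected_k == 2
        assert len(curve.test_ev) == 1

    def test_invalid_k_range_rejected(self):
        with pytest.raises(ValueError):
            cross_validate_k(lambda s: None, ["a"], [], seed=0)
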