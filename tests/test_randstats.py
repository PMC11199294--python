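import itertools

import numpy as np
import pytest

from midstates.microstates import match_templates
from midstates.randstats import (
    _PermutationEngine,
    _interaction_stat,
    _main_effect_stat,
    cell_feature,
    class_analysis_window,
    interaction_test,
    main_effect_test,
    posthoc_contrast,
)

from .conftest import make_tiny_dataset


def planted_model(truth):
    from midstates.microstates import MicrostateModel

    return MicrostateModel(truth.templates)


class TestStatistics:
    def test_additive_table_has_zero_interaction(self):
        table = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert _interaction_stat(table) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_decomposition(self):
        # x_gc = [[1, 2, 3], [6, 5, 4]]; grand mean 3.5
        # row means 2, 5 -> group SS = 1.5^2 + 1.5^2 = 4.5
        # col means 3.5, 3.5, 3.5 -> condition SS = 0
        # residuals: [[-1, 0, 1], [1, 0, -1]] -> interaction SS = 4
        table = np.array([[1.0, 2.0, 3.0], [6.0, 5.0, 4.0]])
        assert _main_effect_stat(table, "group") == pytest.approx(4.5)
        assert _main_effect_stat(table, "condition") == pytest.approx(0.0, abs=1e-12)
        assert _interaction_stat(table) == pytest.approx(4.0)

    def test_statistic_invariant_to_relabeling(self, rng):
        table = rng.normal(size=(2, 3))
        assert _interaction_stat(table) == pytest.approx(
            _interaction_stat(table[::-1]), abs=1e-12
        )
        assert _interaction_stat(table) == pytest.approx(
            _interaction_stat(table[:, ::-1]), abs=1e-12
        )


class TestCellFeature:
    def test_noisefree_duration_matches_planted(self, noisefree_dataset):
        dataset, truth = noisefree_dataset
        model = planted_model(truth)
        # middle class planted from 150 to 350 ms at 200 Hz (5 ms steps);
        # last in-segment sample sits at 345 ms
        d = cell_feature(dataset, model, "patient", "reward", 2,
                         (0.0, 500.0), "duration")
        assert d == pytest.approx(350.0 - 150.0, abs=5.0)

    def test_identical_cells_give_identical_features(self, noisefree_dataset):
        dataset, truth = noisefree_dataset
        model = planted_model(truth)
        vals = {
            (g, c): cell_feature(dataset, model, g, c, 1, (0.0, 500.0), "auc")
            for g in dataset.groups
            for c in dataset.conditions
        }
        assert len({round(v, 9) for v in vals.values()}) == 1

    def test_absent_class_signals_none(self, noisefree_dataset):
        dataset, truth = noisefree_dataset
        model = planted_model(truth)
        # class 3 never appears before 350 ms
        assert cell_feature(dataset, model, "patient", "reward", 3,
                            (0.0, 140.0), "onset") is None


class TestEngineAgainstPublicPath:
    def test_engine_cell_matches_cell_feature(self, tiny_dataset):
        dataset, truth = tiny_dataset
        model = match_templates(planted_model(truth), truth.templates)
        window = (0.0, 500.0)
        eng = _PermutationEngine(dataset, model, 2, window, "duration")
        g0, c0 = eng.identity_assignment()
        table = eng.cell_table(g0, c0)
        for gi, g in enumerate(dataset.groups):
            for ci, c in enumerate(dataset.conditions):
                direct = cell_feature(dataset, model, g, c, 2, window, "duration")
                assert table[gi, ci] == pytest.approx(direct, abs=1e-9)


class TestRandomizationTests:
    def test_identical_cells_give_p_one(self):
        # same data in every cell: observed effect 0 ties with every
        # randomization, so the add-one p-value is exactly 1
        dataset, truth = make_tiny_dataset(noise_sd=0.0)
        base = dataset.get(dataset.subjects[0], "reward")
        for key in dataset.erps:
            dataset.erps[key] = base.copy()
        model = planted_model(truth)
        r = interaction_test(dataset, model, 2, (0.0, 500.0), "duration",
                             n_rand=100, seed=0)
        assert r.observed == pytest.approx(0.0, abs=1e-12)
        assert r.p == 1.0
        m = main_effect_test(dataset, model, 2, (0.0, 500.0), "duration",
                             "group", n_rand=100, seed=0)
        assert m.p == 1.0

    def test_deterministic_given_seed(self, tiny_dataset):
        dataset, truth = tiny_dataset
        model = planted_model(truth)
        r1 = interaction_test(dataset, model, 2, (0.0, 500.0), "auc",
                              n_rand=150, seed=42)
        r2 = interaction_test(dataset, model, 2, (0.0, 500.0), "auc",
                              n_rand=150, seed=42)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)

    def test_small_n_rand_rejected(self, tiny_dataset):
        dataset, truth = tiny_dataset
        with pytest.raises(ValueError):
            interaction_test(dataset, planted_model(truth), 2, (0.0, 500.0),
                             "auc", n_rand=50, seed=0)


class TestPosthocContrast:
    def test_identical_cells_give_p_one(self):
        dataset, truth = make_tiny_dataset(noise_sd=0.0)
        base = dataset.get(dataset.subjects[0], "reward")
        for key in dataset.erps:
            dataset.erps[key] = base.copy()
        model = planted_model(truth)
        r = posthoc_contrast(dataset, model, 2, (0.0, 500.0), "mean_gfp",
                             ("patient", "reward"), ("patient", "neutral"),
                             n_rand=100, seed=0)
        assert r.observed == pytest.approx(0.0, abs=1e-12)
        assert r.p == 1.0

    def test_double_factor_contrast_rejected(self, tiny_dataset):
        dataset, truth = tiny_dataset
        with pytest.raises(ValueError):
            posthoc_contrast(dataset, planted_model(truth), 2, (0.0, 500.0),
                             "auc", ("patient", "reward"), ("control", "neutral"),
                             n_rand=100, seed=0)

    def test_between_group_p_matches_exhaustive_enumeration(self):
        # 4 subjects per group: all C(8,4)=70 group assignments enumerable,
        # so the Monte-Carlo p can be checked against the exact one
        dataset, truth = make_tiny_dataset(n_per_group=(4, 4), noise_sd=0.8,
                                           seed=11)
        model = match_templates(planted_model(truth), truth.templates)
        window = (0.0, 500.0)
        feature = "mean_gfp"
        r = posthoc_contrast(dataset, model, 2, window, feature,
                             ("patient", "reward"), ("control", "reward"),
                             n_rand=3000, seed=1)

        eng = _PermutationEngine(dataset, model, 2, window, feature)
        subjects = np.arange(len(eng.subjects))
        _, cond0 = eng.identity_assignment()
        ci = dataset.conditions.index("reward")
        stats = []
        for combo in itertools.combinations(subjects, 4):
            ga = np.array(combo)
            gb = np.array([s for s in subjects if s not in combo])
            va = eng._cell_value(ga, cond0[ga, ci])
            vb = eng._cell_value(gb, cond0[gb, ci])
            stats.append(abs(va - vb))
        stats = np.array(stats)
        exact_p = np.mean(stats >= r.observed - 1e-12)
        assert abs(r.p - exact_p) < 0.02


class TestClassAnalysisWindow:
    def test_window_covers_planted_segment(self, noisefree_dataset):
        dataset, truth = noisefree_dataset
        model = planted_model(truth)
        w = class_analysis_window(dataset, model, 2)
        assert w is not None
        lo, hi = w
        assert lo == pytest.approx(150.0, abs=5.0)
        assert hi == pytest.approx(345.0, abs=5.0)
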