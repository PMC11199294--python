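import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from midstates.datasets import (
    EpochSet,
    average_epochs,
    average_reference,
    bandpass,
    merge_conditions,
    read_manifest_dataset,
    write_manifest_dataset,
)

from .conftest import make_tiny_dataset


class TestAverageReference:
    @pytest.mark.parametrize(
        "vec,expected",
        [([1, 2, 3], [-1, 0, 1]), ([4, 0, 2], [2, -2, 0])],
    )
    def test_closed_forms(self, vec, expected):
        np.testing.assert_allclose(average_reference(np.array(vec)), expected)

    @given(arrays(float, (6, 4), elements=st.floats(-100, 100)))
    def test_idempotent(self, mat):
        once = average_reference(mat)
        np.testing.assert_allclose(average_reference(once), once, atol=1e-12)
        assert np.all(np.abs(once.mean(axis=0)) < 1e-9)

    def test_linear(self, rng):
        x, y = rng.normal(size=(2, 5, 7))
        a, b = 2.5, -1.25
        np.testing.assert_allclose(
            average_reference(a * x + b * y),
            a * average_reference(x) + b * average_reference(y),
            atol=1e-10,
        )

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            average_reference(np.ones((1, 10)))


def _epochs(sid, cond, n, n_ch=4, n_t=8, fs=256.0, value=None, rng=None):
    if value is not None:
        data = np.full((n, n_ch, n_t), float(value))
    else:
        data = rng.normal(size=(n, n_ch, n_t))
    return EpochSet(sid, cond, data, fs, -500.0)


class TestMergeConditions:
    def test_trial_counts_add(self, rng):
        raw = [
            _epochs("s1", "small_reward", 9, rng=rng),
            _epochs("s1", "large_reward", 9, rng=rng),
            _epochs("s1", "small_loss", 5, rng=rng),
            _epochs("s1", "large_loss", 6, rng=rng),
            _epochs("s1", "neutral", 24, rng=rng),
        ]
        merged = {es.condition: es for es in merge_conditions(raw)}
        assert merged["reward"].n_trials == 18
        assert merged["loss"].n_trials == 11
        assert merged["neutral"].n_trials == 24

    def test_pooled_mean_is_weighted_mean(self, rng):
        small = _epochs("s1", "small_reward", 4, rng=rng)
        large = _epochs("s1", "large_reward", 12, rng=rng)
        merged = merge_conditions([small, large])[0]
        expected = (
            4 * small.epochs.mean(axis=0) + 12 * large.epochs.mean(axis=0)
        ) / 16
        np.testing.assert_allclose(merged.epochs.mean(axis=0), expected, atol=1e-12)

    def test_unknown_label_rejected(self, rng):
        bad = EpochSet("s1", "neutral", np.zeros((1, 4, 8)), 256.0, -500.0)
        bad.condition = "bonus"
        with pytest.raises(ValueError):
            merge_conditions([bad])


class TestAverageEpochs:
    def test_too_few_incentive_trials_excluded(self, rng):
        sets = [
            _epochs("s1", "reward", 8, rng=rng),
            _epochs("s1", "loss", 9, rng=rng),
            _epochs("s1", "neutral", 12, rng=rng),
        ]
        erps, excl = average_epochs(sets)
        assert erps == {}
        assert len(excl) == 1
        assert excl[0].reason == "insufficient_trials"
        assert "reward: 8" in excl[0].detail

    def test_too_few_neutral_trials_excluded(self, rng):
        sets = [
            _epochs("s1", "reward", 9, rng=rng),
            _epochs("s1", "loss", 9, rng=rng),
            _epochs("s1", "neutral", 11, rng=rng),
        ]
        _, excl = average_epochs(sets)
        assert len(excl) == 1 and "neutral: 11" in excl[0].detail

    def test_mean_of_identical_epochs_is_the_epoch(self, rng):
        one = rng.normal(size=(4, 8))
        sets = [
            EpochSet("s1", "reward", np.repeat(one[None], 18, axis=0), 256.0, -500.0),
            _epochs("s1", "loss", 10, rng=rng),
            _epochs("s1", "neutral", 12, rng=rng),
        ]
        erps, excl = average_epochs(sets)
        assert not excl
        np.testing.assert_allclose(erps[("s1", "reward")], average_reference(one), atol=1e-12)

    def test_exclusions_match_brute_force(self, rng):
        sets, expected_excluded = [], set()
        for i in range(12):
            sid = f"s{i}"
            counts = {
                "reward": int(rng.integers(0, 15)),
                "loss": int(rng.integers(0, 15)),
                "neutral": int(rng.integers(0, 20)),
            }
            for cond, n in counts.items():
                if n:
                    sets.append(_epochs(sid, cond, n, rng=rng))
            if (
                counts["reward"] < 9
                or counts["loss"] < 9
                or counts["neutral"] < 12
            ):
                expected_excluded.add(sid)
        erps, excl = average_epochs(sets)
        assert {e.subject_id for e in excl} == expected_excluded
        kept = {sid for sid, _ in erps}
        assert kept.isdisjoint(expected_excluded)


class TestBandpass:
    fs = 256.0

    def _sine(self, hz, n=1024):
        t = np.arange(n) / self.fs
        sig = np.sin(2 * np.pi * hz * t)
        data = np.tile(sig, (1, 2, 1))
        return EpochSet("s1", "neutral", data, self.fs, 0.0)

    def test_passband_preserved(self):
        out = bandpass(self._sine(5.0), 1.0, 15.0)
        mid = out.epochs[0, 0, 256:-256]  # ignore filter edges
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        out = bandpass(self._sine(40.0), 1.0, 15.0)
        mid = out.epochs[0, 0, 256:-256]
        assert np.abs(mid).max() < 0.1

    def test_dc_rejected(self):
        const = EpochSet("s1", "neutral", np.full((1, 2, 512), 7.0), self.fs, 0.0)
        out = bandpass(const, 1.0, 15.0)
        assert np.abs(out.epochs).max() < 1e-6

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(self._sine(5.0), 15.0, 1.0)


class TestManifestIO:
    def test_round_trip_lossless(self, tmp_path):
        dataset, _ = make_tiny_dataset(n_per_group=(2, 2))
        import pandas as pd

        dataset.clinical = pd.DataFrame(
            {"anticipatory": 1.0, "consummatory": 2.0, "covariate": 3.0},
            index=pd.Index(dataset.subjects, name="subject_id"),
        )
        write_manifest_dataset(dataset, tmp_path / "ds")
        back = read_manifest_dataset(tmp_path / "ds")
        assert back.subjects == dataset.subjects
        assert back.groups == dataset.groups
        for key, mat in dataset.erps.items():
            np.testing.assert_allclose(back.erps[key], mat, atol=1e-9)
        np.testing.assert_allclose(back.times, dataset.times, atol=1e-9)
        assert back.clinical is not None

    def test_all_columns_average_referenced(self, tmp_path):
        dataset, _ = make_tiny_dataset(n_per_group=(2, 2))
        write_manifest_dataset(dataset, tmp_path / "ds")
        back = read_manifest_dataset(tmp_path / "ds")
        for mat in back.erps.values():
            assert np.abs(mat.mean(axis=0)).max() < 1e-9

    def test_missing_matrix_file_named_in_error(self, tmp_path):
        dataset, _ = make_tiny_dataset(n_per_group=(2, 2))
        root = write_manifest_dataset(dataset, tmp_path / "ds")
        victim = root / "erp_S001_reward.tsv"
        victim.unlink()
        with pytest.raises(FileNotFoundError, match="S001"):
            read_manifest_dataset(root)
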