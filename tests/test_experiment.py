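import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tifpscreen.experiment import (
    ActivityRecord,
    GridSpec,
    PoseRecord,
    assign_label,
    filter_poses,
    grid_search,
    p_activity,
    pairwise_similarity,
    repeated_training,
    split_dataset,
    tanimoto,
)
from tifpscreen.network import ModelConfig
from tifpscreen.synthetic import FingerprintDatasetSpec, make_fingerprint_dataset


class TestLabels:
    @pytest.mark.parametrize("value_um,expected", [
        (10.0, "positive"),      # at the positive boundary
        (50.1, "negative"),      # just past the negative boundary
        (25.0, "excluded"),      # inside the gap
        (0.001, "positive"),
        (50.0, "excluded"),      # boundary of the gap, not yet negative
    ])
    def test_threshold_rule(self, value_um, expected):
        assert assign_label(value_um * 1000.0) == expected

    def test_record_interface_and_errors(self):
        rec = ActivityRecord("m1", "DOT1L", "IC50", 10_000.0)
        assert assign_label(rec) == "positive"
        with pytest.raises(ValueError):
            assign_label(-5.0)
        with pytest.raises(ValueError):
            ActivityRecord("m1", "DOT1L", "Kd", 10.0)

    @pytest.mark.parametrize("nm,expected", [(1.0, 9.0), (1000.0, 6.0), (10_000.0, 5.0)])
    def test_p_activity(self, nm, expected):
        assert p_activity(nm) == pytest.approx(expected)
        rec = ActivityRecord("m", "t", "Ki", nm)
        assert rec.p_activity == pytest.approx(expected)

    def test_p_activity_nonpositive_errors(self):
        with pytest.raises(ValueError):
            p_activity(0.0)


class TestPoseFilter:
    def _pose(self, mid, score, offset):
        return PoseRecord(mid, "t", score, (offset, 0.0, 0.0), (0.0, 0.0, 0.0))

    def test_threshold_and_pocket_rules(self):
        poses = [
            self._pose("keep", -9.0, 3.0),
            self._pose("weak", -7.0, 3.0),     # score above threshold
            self._pose("far", -9.0, 12.0),     # outside the pocket
        ]
        kept = filter_poses(poses, score_max=-8.2, pocket_radius=8.0)
        assert [p.molecule_id for p in kept] == ["keep"]

    def test_best_pose_per_molecule(self):
        poses = [self._pose("m", -8.5, 1.0), self._pose("m", -9.5, 2.0),
                 self._pose("m", -8.9, 1.5)]
        kept = filter_poses(poses)
        assert len(kept) == 1 and kept[0].docking_score == -9.5

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(0)
        poses = [self._pose(f"m{i % 7}", float(rng.uniform(-11, -6)), float(rng.uniform(0, 12)))
                 for i in range(40)]
        kept = filter_poses(poses)
        assert set(p.molecule_id for p in kept) <= {f"m{i}" for i in range(7)}
        assert len({p.molecule_id for p in kept}) == len(kept)
        assert all(p in poses for p in kept)


class TestSplitProtocol:
    def test_published_dataset_size_partition(self):
        splits = split_dataset(list(range(1740)), seed=7)
        assert len(splits) == 10
        for s in splits:
            assert (len(s.test_ids), len(s.valid_ids), len(s.train_ids)) == (158, 176, 1406)

    def test_test_set_fixed_across_repeats(self):
        splits = split_dataset(list(range(300)), seed=1)
        tests = {s.test_ids for s in splits}
        assert len(tests) == 1
        assert len({s.valid_ids for s in splits}) > 1

    def test_seed_reproducibility(self):
        a = split_dataset(list(range(500)), seed=9)
        b = split_dataset(list(range(500)), seed=9)
        assert all(x.valid_ids == y.valid_ids and x.train_ids == y.train_ids
                   for x, y in zip(a, b))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(22, 5000), seed=st.integers(0, 2**20))
    def test_partition_property_fuzzed(self, n, seed):
        splits = split_dataset(list(range(n)), seed=seed, n_repeats=3)
        for s in splits:
            parts = [set(s.test_ids), set(s.valid_ids), set(s.train_ids)]
            assert all(p for p in parts)
            assert sum(len(p) for p in parts) == n
            assert set.union(*parts) == set(range(n))

    def test_too_few_ids_errors(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(21)), seed=0)

    def test_alternative_plain_fraction_reading(self):
        splits = split_dataset(list(range(1000)), seed=0, test_fraction=0.1)
        assert len(splits[0].test_ids) == 100


def tiny_dataset(seed=0, n=160):
    ds = make_fingerprint_dataset(FingerprintDatasetSpec(
        n_samples=n, n_features=20, n_signal_bits=6, seed=seed))
    return ds.X, ds.y


class TestGridSearch:
    def test_single_cell_grid(self):
        X, y = tiny_dataset()
        grid = GridSpec(dropouts=(0.1,), learning_rates=(0.001,), hidden_sizes=((8, 8),))
        base = ModelConfig(input_dim=20, hidden_sizes=(8, 8), max_epochs=4, batch_size=32)
        results, best = grid_search(grid, (X[:120], y[:120]), (X[120:], y[120:]), base)
        assert len(results) == 1
        assert best["dropout"] == 0.1 and best["learning_rate"] == 0.001

    def test_row_count_is_axis_product(self):
        X, y = tiny_dataset(1)
        grid = GridSpec(dropouts=(0.1, 0.2), learning_rates=(0.001, 0.0005),
                        hidden_sizes=((8, 8),))
        base = ModelConfig(input_dim=20, max_epochs=3, batch_size=32)
        results, _ = grid_search(grid, (X[:120], y[:120]), (X[120:], y[120:]), base)
        assert len(results) == grid.n_combinations == 4
        expected_cols = {
            "stop_epoch",
            "train_recall", "train_precision", "train_roc_auc", "train_prc_auc",
            "valid_recall", "valid_precision", "valid_roc_auc", "valid_prc_auc",
        }
        assert expected_cols <= set(results.columns)

    def test_best_is_validation_prc_argmax(self):
        X, y = tiny_dataset(2)
        grid = GridSpec(dropouts=(0.0, 0.3), learning_rates=(0.001,), hidden_sizes=((8, 8),))
        base = ModelConfig(input_dim=20, max_epochs=4, batch_size=32)
        results, best = grid_search(grid, (X[:120], y[:120]), (X[120:], y[120:]), base)
        top = results.sort_values(["valid_prc_auc", "dropout"], ascending=[False, True]).iloc[0]
        assert best["valid_prc_auc"] == top["valid_prc_auc"]

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(dropouts=())


class TestRepeatedTraining:
    def test_summary_matches_hand_computation(self):
        X, y = tiny_dataset(3, n=180)
        ids = list(range(180))
        splits = split_dataset(ids, seed=0, n_repeats=3)
        cfg = ModelConfig(input_dim=20, hidden_sizes=(8, 8), max_epochs=4,
                          batch_size=32, seed=0)
        per_split, summary, best_index, models = repeated_training(cfg, splits, X, y, ids)
        assert len(per_split) == 3 and len(models) == 3
        for metric in ("recall", "precision", "accuracy", "roc_auc", "prc_auc"):
            vals = per_split[metric].to_numpy()
            assert summary.loc[metric, "mean"] == pytest.approx(np.mean(vals), abs=1e-12)
            assert summary.loc[metric, "sd"] == pytest.approx(np.std(vals, ddof=1), abs=1e-12)
        assert best_index == int(np.argmax(per_split["prc_auc"].to_numpy()))

    def test_fewer_than_two_splits_rejected(self):
        X, y = tiny_dataset(4)
        ids = list(range(160))
        splits = split_dataset(ids, seed=0, n_repeats=1)
        with pytest.raises(ValueError, match="2 splits"):
            repeated_training(ModelConfig(input_dim=20), splits, X, y, ids)


class TestSimilarity:
    def test_identical_and_disjoint_bitsets(self):
        assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0
        assert tanimoto({1, 2}, {3, 4}) == 0.0
        with pytest.raises(ValueError):
            tanimoto(set(), {1})

    def test_pair_count_and_histogram(self):
        rng = np.random.default_rng(0)
        bitsets = [set(rng.choice(64, 12, replace=False)) for _ in range(10)]
        coeffs, counts, edges = pairwise_similarity(bitsets, n_hist_bins=20)
        assert len(coeffs) == 45  # C(10, 2)
        assert counts.sum() == 45 and len(edges) == 21
        assert np.all((coeffs >= 0) & (coeffs <= 1))
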