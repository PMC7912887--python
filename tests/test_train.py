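from collections import Counter

import numpy as np
import pytest
from helpers import FAST_RULE, quick_train, small_spec

from mirtarnet.codec import LabeledPair, MIRAW_SCHEMA, RnaSequence, encode_dataset
from mirtarnet.model import build_model
from mirtarnet.train import (
    EarlyStopRule,
    HyperGrid,
    SplitSpec,
    TrainError,
    compose_unified_dataset,
    grid_search,
    repeated_runs,
    run_cell,
    split_dataset,
    split_sizes,
    train_once,
)

MIRNA = "AUGCAUGCAUGCAUGCAUGC"
SITE = "GCAUGCAUGCAUGCAUGCAUGCAUGCAUGCAUGCAUGCAU"


def dummy_pairs(n_pos, n_neg):
    return [
        LabeledPair(RnaSequence(MIRNA), RnaSequence(SITE), 1, f"p{i}")
        for i in range(n_pos)
    ] + [
        LabeledPair(RnaSequence(MIRNA), RnaSequence(SITE), 0, f"n{i}")
        for i in range(n_neg)
    ]


class TestSplitDataset:
    def test_table1_deepmirtar_test_count(self):
        # N = 7,758 (3,908 positive / 3,850 negative) -> 1,552 test pairs
        pairs = dummy_pairs(3908, 3850)
        splits = split_dataset(pairs, SplitSpec(seed=0))
        assert len(splits.test) == 1552
        assert len(splits.val) == 1241

    def test_table1_mirtarraw_test_count(self):
        # N = 27,720 balanced -> 5,544 test pairs
        pairs = dummy_pairs(13860, 13860)
        splits = split_dataset(pairs, SplitSpec(seed=1))
        assert len(splits.test) == 5544

    def test_split_sizes_round_convention(self):
        assert split_sizes(7758, SplitSpec()) == (4965, 1241, 1552)
        # train is the remainder, so it exceeds the published row (which
        # sums to one less than N) by exactly one pair
        assert split_sizes(27720, SplitSpec()) == (17741, 4435, 5544)

    def test_disjoint_cover(self):
        pairs = dummy_pairs(60, 40)
        # give every pair a unique id for multiset bookkeeping
        pairs = [
            LabeledPair(p.mirna, p.site, p.label, f"{p.pair_id}_{i}")
            for i, p in enumerate(pairs)
        ]
        splits = split_dataset(pairs, SplitSpec(seed=3))
        ids = [p.pair_id for p in splits.train + splits.val + splits.test]
        assert Counter(ids) == Counter(p.pair_id for p in pairs)

    def test_stratified_by_label(self):
        splits = split_dataset(dummy_pairs(100, 100), SplitSpec(seed=2))
        test_labels = Counter(p.label for p in splits.test)
        assert test_labels[0] == test_labels[1] == 20

    def test_same_seed_identical(self):
        pairs = dummy_pairs(50, 50)
        a = split_dataset(pairs, SplitSpec(seed=7))
        b = split_dataset(pairs, SplitSpec(seed=7))
        assert [p.pair_id for p in a.test] == [p.pair_id for p in b.test]
        assert [p.pair_id for p in a.train] == [p.pair_id for p in b.train]

    def test_different_seed_differs(self):
        pairs = dummy_pairs(200, 200)
        a = split_dataset(pairs, SplitSpec(seed=7))
        b = split_dataset(pairs, SplitSpec(seed=8))
        assert [p.pair_id for p in a.test] != [p.pair_id for p in b.test]

    def test_empty_split_error(self):
        with pytest.raises(TrainError):
            split_dataset(dummy_pairs(2, 2), SplitSpec(seed=0))

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(train_frac=0.5, val_frac=0.2, test_frac=0.2)


class TestTrainOnce:
    def _tiny_data(self, rng, n=40, length=66):
        X = rng.integers(0, 5, size=(n, length))
        y = rng.integers(0, 2, size=n).astype(float)
        return (X[: n // 2], y[: n // 2]), (X[n // 2 :], y[n // 2 :])

    def test_zero_learning_rate_keeps_weights(self, rng):
        net = build_model(small_spec(), rng=0)
        before = net.get_weights()
        splits = self._tiny_data(rng)
        record = train_once(net, splits, learning_rate=0.0, batch_size=10,
                            rule=EarlyStopRule(patience=2), max_epochs=3)
        after = net.get_weights()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        assert record.epochs_run <= 3

    def test_patience_fires_before_max_epochs(self, rng):
        net = build_model(small_spec(dropout=0.0), rng=0)
        splits = self._tiny_data(rng)
        # min_delta so large that no improvement can reset the clock
        rule = EarlyStopRule(min_delta=0.5, patience=3)
        record = train_once(net, splits, learning_rate=0.001, batch_size=10,
                            rule=rule, max_epochs=50)
        assert record.epochs_run < 50

    def test_never_exceeds_max_epochs(self, rng):
        net = build_model(small_spec(), rng=1)
        record = train_once(net, self._tiny_data(rng), learning_rate=0.01,
                            batch_size=10, rule=EarlyStopRule(patience=100),
                            max_epochs=4)
        assert record.epochs_run == 4

    def test_planted_signal_recovered(self, small_synth_pairs):
        """Scaled-down planted-seed run: the model must beat 0.85."""
        record, _ = quick_train(small_synth_pairs, seed=0)
        assert record.best_val_accuracy >= 0.85
        assert record.test_report.accuracy >= 0.85

    def test_best_weights_restored(self, small_synth_pairs):
        record, net = quick_train(small_synth_pairs, seed=1, max_epochs=6)
        splits = split_dataset(small_synth_pairs, SplitSpec(seed=1))
        X_val, y_val = encode_dataset(splits.val, MIRAW_SCHEMA)
        acc = float(np.mean((net.predict(X_val) >= 0.5) == (y_val == 1)))
        assert acc == pytest.approx(record.best_val_accuracy)


class TestGridSearch:
    def test_single_cell_returned(self, small_synth_pairs):
        grid = HyperGrid(learning_rates=(0.005,), dropout_rates=(0.2,),
                         batch_sizes=(50,), max_epochs=2)
        best, board = grid_search(
            small_synth_pairs[:200], grid, SplitSpec(seed=0), MIRAW_SCHEMA,
            base_spec=small_spec(), rule=FAST_RULE,
        )
        assert (best["learning_rate"], best["dropout_rate"], best["batch_size"]) == (
            0.005, 0.2, 50,
        )
        assert len(board) == 1

    def test_degenerate_cell_loses(self, small_synth_pairs):
        grid = HyperGrid(learning_rates=(0.0, 0.005), dropout_rates=(0.2,),
                         batch_sizes=(50,), max_epochs=8)
        best, board = grid_search(
            small_synth_pairs, grid, SplitSpec(seed=0), MIRAW_SCHEMA,
            base_spec=small_spec(), rule=FAST_RULE,
        )
        assert best["learning_rate"] == 0.005
        assert len(board) == 2

    def test_full_grid_is_cartesian_product(self):
        assert len(HyperGrid().cells()) == 6 * 5 * 5

    def test_empty_grid_error(self, small_synth_pairs):
        grid = HyperGrid(learning_rates=(), dropout_rates=(), batch_sizes=())
        with pytest.raises(TrainError):
            grid_search(small_synth_pairs, grid, SplitSpec(seed=0), MIRAW_SCHEMA)


class TestRepeatedRuns:
    def test_two_repeats_distinct_seeds(self, small_synth_pairs):
        reports, records = repeated_runs(
            small_synth_pairs[:300], MIRAW_SCHEMA, 0.005, 0.2, 50,
            n_repeats=2, master_seed=0, base_spec=small_spec(),
            rule=FAST_RULE, max_epochs=3,
        )
        assert len(reports) == 2
        assert records[0].split_seed != records[1].split_seed

    def test_forced_identical_seeds_identical_reports(self, small_synth_pairs):
        reports, _ = repeated_runs(
            small_synth_pairs[:300], MIRAW_SCHEMA, 0.005, 0.2, 50,
            n_repeats=2, base_spec=small_spec(), rule=FAST_RULE,
            max_epochs=3, split_seeds=[11, 11],
        )
        assert reports[0] == reports[1]

    def test_min_repeats(self, small_synth_pairs):
        with pytest.raises(TrainError):
            repeated_runs(small_synth_pairs, MIRAW_SCHEMA, 0.005, 0.2, 50, n_repeats=1)

    def test_mean_close_to_single_run(self, small_synth_pairs):
        """3-repeat mean within 5 points of a single run on the same data."""
        single, _ = quick_train(small_synth_pairs, seed=0)
        reports, _ = repeated_runs(
            small_synth_pairs, MIRAW_SCHEMA, 0.01, 0.2, 30,
            n_repeats=3, master_seed=1, base_spec=small_spec(),
            rule=FAST_RULE, max_epochs=20,
        )
        mean_acc = float(np.mean([r.accuracy for r in reports]))
        assert abs(mean_acc - single.test_report.accuracy) <= 0.05


class TestComposeUnified:
    def test_paper_counts(self):
        dmt = dummy_pairs(3908, 3850)
        mrw = dummy_pairs(31660, 30993)
        out = compose_unified_dataset(dmt, mrw, frac_dmt=0.90, cap_ratio=3, seed=0)
        combined = out["mirtarraw"]
        assert len(combined) == 27720
        dmt_left_pos = sum(p.label for p in out["deepmirtar_left"])
        mrw_left_pos = sum(p.label for p in out["miraw_left"])
        assert dmt_left_pos == 443
        assert len(out["deepmirtar_left"]) - dmt_left_pos == 385
        assert mrw_left_pos == 21265
        assert len(out["miraw_left"]) - mrw_left_pos == 20598

    def test_combined_is_balanced(self):
        out = compose_unified_dataset(
            dummy_pairs(100, 90), dummy_pairs(500, 480), seed=1
        )
        labels = Counter(p.label for p in out["mirtarraw"])
        assert labels[0] == labels[1]

    def test_frac_one_big_cap_leaves_nothing_from_first_pool(self):
        out = compose_unified_dataset(
            dummy_pairs(50, 50), dummy_pairs(1000, 1000),
            frac_dmt=1.0, cap_ratio=1000, seed=0,
        )
        assert out["deepmirtar_left"] == []
        assert out["miraw_left"] == []

    def test_zero_draw_error(self):
        with pytest.raises(TrainError):
            compose_unified_dataset(
                dummy_pairs(10, 10), dummy_pairs(10, 10), frac_dmt=0.01
            )


class TestRunCellDeterminism:
    def test_same_seed_same_result(self, small_synth_pairs):
        a, _ = quick_train(small_synth_pairs[:200], seed=5, max_epochs=3)
        b, _ = quick_train(small_synth_pairs[:200], seed=5, max_epochs=3)
        assert a.test_report == b.test_report
        assert a.history == b.history
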