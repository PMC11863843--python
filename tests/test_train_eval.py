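import numpy as np
import pytest

from irfg.errors import TrainingDivergenceError
from irfg.split_net import SplitNet, SplitNetConfig
from irfg.train_eval import (
    TrainConfig,
    cross_validate,
    fpr_fnr_table,
    holdout_protocol,
    kfold_split,
    lr_at_epoch,
    macro_f1,
    per_group_f1,
    perfect_match_table,
    train,
)

from _oracles import brute_force_f1

N = 17


@pytest.fixture(scope="module")
def random_instances():
    rng = np.random.default_rng(99)
    pred = rng.integers(0, 2, (200, N))
    lab = rng.integers(0, 2, (200, N))
    # plant degenerate columns: never present, never predicted
    pred[:, 5] = 0
    lab[:, 5] = 0
    return pred, lab


class TestKfoldSplit:
    def test_five_disjoint_validation_pairs(self):
        folds = kfold_split(10, 5, seed=0)
        assert len(folds) == 5
        for tr, va in folds:
            assert va.size == 2 and tr.size == 8
            assert np.intersect1d(tr, va).size == 0

    def test_validation_folds_partition_everything(self):
        folds = kfold_split(23, 5, seed=1)
        all_va = np.concatenate([va for _, va in folds])
        assert sorted(all_va) == list(range(23))
        sizes = [va.size for _, va in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_folds(self):
        a, b = kfold_split(50, 5, seed=3), kfold_split(50, 5, seed=3)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(va, vb)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(10, 1)


class TestMetricsAgainstBruteForce:
    def test_f1_formula(self):
        pred = np.zeros((4, N), dtype=int)
        lab = np.zeros((4, N), dtype=int)
        # group 0: TP=2, FP=1, FN=1
        pred[:, 0] = [1, 1, 1, 0]
        lab[:, 0] = [1, 1, 0, 1]
        assert per_group_f1(pred, lab)[0] == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        rng = np.random.default_rng(1)
        lab = rng.integers(0, 2, (50, N))
        f1 = per_group_f1(lab, lab)
        defined = ~np.isnan(f1)
        assert np.all(f1[defined] == 1.0)

    def test_undefined_groups_excluded_from_macro(self, random_instances):
        pred, lab = random_instances
        f1 = per_group_f1(pred, lab)
        assert np.isnan(f1[5])
        assert np.isfinite(macro_f1(pred, lab))

    def test_f1_matches_brute_force(self, random_instances):
        pred, lab = random_instances
        np.testing.assert_allclose(
            per_group_f1(pred, lab), brute_force_f1(pred, lab), atol=1e-12
        )

    def test_perfect_match_table_brute_force(self, random_instances):
        pred, lab = random_instances
        table = perfect_match_table(pred, lab)
        assert int(table["n_samples"].sum()) == 200
        for g, row in table.iterrows():
            mask = lab.sum(axis=1) == g
            exact = [(pred[i] == lab[i]).all() for i in np.flatnonzero(mask)]
            assert row["n_perfect"] == sum(exact)
            assert row["ratio"] == pytest.approx(np.mean(exact), abs=1e-12)

    def test_fpr_fnr_table_brute_force(self, random_instances):
        pred, lab = random_instances
        table = fpr_fnr_table(pred, lab)
        for g, row in table.iterrows():
            fprs, fnrs = [], []
            for i in np.flatnonzero(lab.sum(axis=1) == g):
                fp = np.sum(pred[i] & ~lab[i])
                tn = np.sum(~pred[i].astype(bool) & ~lab[i].astype(bool))
                fn = np.sum(~pred[i].astype(bool) & lab[i].astype(bool))
                tp = np.sum(pred[i] & lab[i])
                if fp + tn:
                    fprs.append(fp / (fp + tn))
                if fn + tp:
                    fnrs.append(fn / (fn + tp))
            if fprs:
                assert row["fpr"] == pytest.approx(np.mean(fprs), abs=1e-12)
            if fnrs:
                assert row["fnr"] == pytest.approx(np.mean(fnrs), abs=1e-12)

    def test_single_positive_prediction_on_empty_sample(self):
        pred = np.zeros((1, N), dtype=int)
        pred[0, 3] = 1
        lab = np.zeros((1, N), dtype=int)
        table = fpr_fnr_table(pred, lab)
        assert table.loc[0, "fpr"] == pytest.approx(1 / 17)
        assert np.isnan(table.loc[0, "fnr"])

    def test_perfect_match_bounded_by_groupwise_accuracy(self, random_instances):
        pred, lab = random_instances
        pm_ratio = float((pred == lab).all(axis=1).mean())
        acc = (pred == lab).mean(axis=0)
        assert pm_ratio <= acc.min() + 1e-12


class TestLrSchedule:
    def test_linear_decay_checkpoints(self):
        cfg = TrainConfig(epochs=50, base_lr=1e-3)
        assert lr_at_epoch(cfg, 0) == pytest.approx(1e-3)
        assert lr_at_epoch(cfg, 25) == pytest.approx(5e-4)
        assert lr_at_epoch(cfg, 40) == pytest.approx(2e-4)
        assert lr_at_epoch(cfg, 49) < lr_at_epoch(cfg, 0)


def _separable_batch(tiny_grid, n_copies=50):
    """One synthetic sample repeated: a peak on the FP side labels class 0."""
    x = np.exp(-0.5 * ((tiny_grid - 1020) / 5) ** 2).astype(np.float32)
    y = np.zeros(17, dtype=np.float32)
    y[0] = 1
    return np.tile(x, (n_copies, 1)), np.tile(y, (n_copies, 1))


class TestTraining:
    def test_overfits_single_separable_sample(self, tiny_grid):
        xs, ys = _separable_batch(tiny_grid)
        cfg = SplitNetConfig(boundary=1050.0, head_hidden=8, concat_size=16, seed=0)
        net = SplitNet(cfg, tiny_grid)
        hist = train(
            (xs, ys), net, TrainConfig(epochs=50, base_lr=0.05, batch_size=8, seed=0)
        )
        assert hist[-1] < 0.01

    def test_loss_history_bookkeeping(self, tiny_grid):
        xs, ys = _separable_batch(tiny_grid, 8)
        cfg = SplitNetConfig(boundary=1050.0, head_hidden=4, concat_size=8, seed=0)
        net = SplitNet(cfg, tiny_grid)
        hist = train((xs, ys), net, TrainConfig(epochs=5, seed=0))
        assert len(hist) == 5

    def test_fixed_seed_reproducible_history(self, tiny_grid):
        xs, ys = _separable_batch(tiny_grid, 16)

        def run():
            cfg = SplitNetConfig(boundary=1050.0, head_hidden=4, concat_size=8, seed=2)
            net = SplitNet(cfg, tiny_grid)
            return train((xs, ys), net, TrainConfig(epochs=4, seed=2))

        assert run() == run()

    def test_divergence_raises_with_epoch(self, tiny_grid):
        xs, ys = _separable_batch(tiny_grid, 8)
        cfg = SplitNetConfig(boundary=1050.0, head_hidden=4, concat_size=8, seed=0)
        net = SplitNet(cfg, tiny_grid)
        with pytest.raises(TrainingDivergenceError):
            train((xs, ys), net, TrainConfig(epochs=5, base_lr=1e30, seed=0))


def _toy_records(tiny_grid, n=40, seed=0):
    """Records where class 0 presence == peak at 1020 cm^-1, class 7 == 1100."""
    from irfg.preprocess import DatasetRecord, Spectrum

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        labels = np.zeros(17, dtype=np.int8)
        y = np.zeros(tiny_grid.size)
        if rng.random() < 0.5:
            labels[0] = 1
            y += np.exp(-0.5 * ((tiny_grid - 1020) / 5) ** 2)
        if rng.random() < 0.5:
            labels[7] = 1
            y += np.exp(-0.5 * ((tiny_grid - 1100) / 5) ** 2)
        y = np.clip(y + rng.normal(0, 0.01, tiny_grid.size), 0, 1)
        records.append(DatasetRecord(f"t{i}", None, Spectrum(tiny_grid, y), labels))
    return records


class TestProtocols:
    def test_cross_validate_report_shape(self, tiny_grid):
        records = _toy_records(tiny_grid)
        cfg = SplitNetConfig(boundary=1050.0, head_hidden=8, concat_size=16, seed=0)
        report = cross_validate(
            records, cfg, TrainConfig(epochs=40, base_lr=0.05, batch_size=8, seed=0)
        )
        assert report.f1_mean.shape == (17,)
        assert report.f1_sd.shape == (17,)
        assert int(report.perfect_match["n_samples"].sum()) == len(records)
        # the two encoded classes should be learned well on this easy problem
        assert report.f1_mean[0] > 0.9 and report.f1_mean[7] > 0.9

    def test_holdout_sizes_and_disjointness(self, tiny_grid):
        records = _toy_records(tiny_grid, n=50)
        cfg = SplitNetConfig(boundary=1050.0, head_hidden=4, concat_size=8, seed=0)
        report, test_idx = holdout_protocol(
            records, cfg, TrainConfig(epochs=2, seed=0)
        )
        assert test_idx.size == 5  # 10% of 50
        assert report.fold_f1.shape == (5, 17)

    def test_holdout_same_seed_same_test_set(self, tiny_grid):
        records = _toy_records(tiny_grid, n=30)
        cfg = SplitNetConfig(boundary=1050.0, head_hidden=4, concat_size=8, seed=1)
        _, a = holdout_protocol(records, cfg, TrainConfig(epochs=1, seed=5))
        _, b = holdout_protocol(records, cfg, TrainConfig(epochs=1, seed=5))
        np.testing.assert_array_equal(a, b)
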