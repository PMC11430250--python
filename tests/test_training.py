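"""Splits, metrics, training loop bookkeeping, baselines and noise sweeps."""

import numpy as np
import pandas as pd
import pytest

import dfcgn
from dfcgn.core import EpochSet
from dfcgn.training import (
    TrainConfig,
    add_noise_at_snr,
    evaluate_predictions,
    handcrafted_features,
    metrics_from_counts,
    roc_points,
    split_epochs,
)


def _toy_epochs(n_pos, n_neg, n_samples=16, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    return EpochSet(
        epochs=rng.normal(size=(n, 2, n_samples)),
        labels=np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)],
        fs=128.0,
        channel_names=["a", "b"],
    )


class TestSplit:
    def test_published_fractions_at_n100(self):
        tr, va, te = split_epochs(_toy_epochs(50, 50), TrainConfig(seed=0))
        assert (tr.n_epochs, va.n_epochs, te.n_epochs) == (70, 20, 10)

    def test_small_balanced_set_rounds_to_7_2_1(self):
        tr, va, te = split_epochs(_toy_epochs(5, 5), TrainConfig(seed=0))
        assert (tr.n_epochs, va.n_epochs, te.n_epochs) == (7, 2, 1)
        assert set(tr.labels) == {0, 1}

    def test_splits_are_stratified_and_disjoint(self, epochs_small):
        tr, va, te = split_epochs(epochs_small, TrainConfig(seed=1))
        for part in (tr, va, te):
            assert set(part.labels) <= {0, 1}
        assert tr.n_epochs + va.n_epochs + te.n_epochs == epochs_small.n_epochs
        # class balance preserved within one epoch per split
        for part in (tr, va):
            assert abs((part.labels == 1).sum() - (part.labels == 0).sum()) <= 1

    def test_same_seed_same_partition(self, epochs_small):
        a = split_epochs(epochs_small, TrainConfig(seed=5))
        b = split_epochs(epochs_small, TrainConfig(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.epochs, y.epochs)

    def test_too_few_epochs_advises_windowing(self):
        with pytest.raises(ValueError, match="windowing"):
            split_epochs(_toy_epochs(2, 2), TrainConfig(seed=0))

    def test_split_fractions_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrainConfig(split=(0.8, 0.1, 0.2))


def brute_force_metrics(y_true, y_pred):
    """Independent oracle: metric definitions evaluated by explicit loops."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    n = len(y_true)
    acc = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": acc,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "kappa": 0.0 if pe == 1.0 else (acc - pe) / (1 - pe),
    }


class TestMetrics:
    def test_identities_on_randomized_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, size=n)
            p = rng.integers(0, 2, size=n)
            rep = evaluate_predictions(y, p)
            want = brute_force_metrics(y, p)
            for key, val in want.items():
                assert getattr(rep, key) == pytest.approx(val, abs=1e-12), key

    def test_hand_computed_confusion_example(self):
        m = metrics_from_counts(tp=45, fp=10, tn=40, fn=5)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["precision"] == pytest.approx(45 / 55)
        assert m["specificity"] == pytest.approx(0.80)
        assert m["kappa"] == pytest.approx(0.70)

    def test_perfect_and_chance_kappa(self):
        assert metrics_from_counts(50, 0, 50, 0)["kappa"] == pytest.approx(1.0)
        # label-independent 50/50 predictions on a balanced set
        assert metrics_from_counts(25, 25, 25, 25)["kappa"] == pytest.approx(0.0)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score, roc_auc_score

        for _ in range(25):
            n = 80
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            pred = rng.integers(0, 2, size=n)
            scores = rng.random(n)
            rep = evaluate_predictions(y, pred, scores)
            assert rep.kappa == pytest.approx(cohen_kappa_score(y, pred), abs=1e-12)
            assert rep.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_roc_endpoints_and_random_scorer_auc(self, rng):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
            fpr, tpr, auc = roc_points(r.random(200), y)
            assert fpr[0] == 0.0 and tpr[0] == 0.0
            assert fpr[-1] == 1.0 and tpr[-1] == 1.0
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_test_set_omits_roc(self):
        y = np.ones(10, dtype=int)
        with pytest.warns(RuntimeWarning, match="single-class"):
            rep = evaluate_predictions(y, y, np.linspace(0, 1, 10))
        assert rep.auc is None
        assert rep.accuracy == 1.0


class TestHandcraftedFeatures:
    def test_unit_sine_closed_forms(self):
        t = np.arange(1024) / 1024.0
        sine = np.sin(2 * np.pi * 8 * t)
        es = EpochSet(sine[None, None, :], np.array([1]), 1024.0, ["a"])
        row = handcrafted_features(es).iloc[0]
        assert row["a_mean"] == pytest.approx(0.0, abs=1e-12)
        assert row["a_power"] == pytest.approx(0.5, rel=1e-6)
        assert row["a_crest"] == pytest.approx(np.sqrt(2), rel=1e-3)

    def test_constant_epoch_degenerate_stats_flagged(self):
        es = EpochSet(np.full((1, 1, 64), 3.0), np.array([0]), 128.0, ["a"])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            row = handcrafted_features(es).iloc[0]
        assert row["a_variance"] == 0.0
        assert row["a_power"] == pytest.approx(9.0)
        assert row["a_skewness"] == 0.0 and row["a_crest"] == 0.0

    def test_one_row_per_epoch_six_features_per_channel(self, epochs_small):
        df = handcrafted_features(epochs_small)
        assert len(df) == epochs_small.n_epochs
        assert df.shape[1] == 6 * epochs_small.n_channels + 1  # + label


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_weights_unchanged(self, epochs_small):
        cfg = TrainConfig(lr=0.0, ft2_xi=0.0, epochs=2, seed=0)
        tr, va, _ = split_epochs(epochs_small, cfg)
        G = dfcgn.graph_from_epochs(tr, tau=0.5)
        model = dfcgn.DFCGN(dfcgn.reduced_config(), G, seed=0)
        model.fit_scaler(tr.epochs)
        model.calibrate_scales(tr.epochs)
        before = {k: v.copy() for k, v in model.weight_params().items()}
        model, _ = dfcgn.train(model, tr, va, cfg)
        for k, v in model.weight_params().items():
            np.testing.assert_array_equal(v, before[k])

    def test_history_has_one_row_per_epoch(self, trained_small):
        assert len(trained_small["history"]) == trained_small["cfg"].epochs

    def test_training_is_reproducible(self, epochs_small):
        cfg = TrainConfig(optimizer="adam", lr=1e-3, epochs=3, seed=9)
        histories = []
        for _ in range(2):
            tr, va, _ = split_epochs(epochs_small, cfg)
            G = dfcgn.graph_from_epochs(tr, tau=0.5)
            model = dfcgn.DFCGN(dfcgn.reduced_config(), G, seed=9)
            _, hist = dfcgn.train(model, tr, va, cfg)
            histories.append(hist)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_trained_model_beats_chance(self, trained_small):
        rep = dfcgn.evaluate(trained_small["model"], trained_small["test"])
        assert rep.accuracy > 0.6
        assert rep.auc is not None and rep.auc > 0.6


class TestNoiseRobustness:
    def test_noise_scale_definition_is_exact(self, rng):
        X = rng.normal(size=(5, 3, 64)) * 4.0
        noisy = add_noise_at_snr(X, 0.0, np.random.default_rng(77))
        p_sig = np.mean(X**2, axis=(1, 2), keepdims=True)
        expected = X + np.sqrt(p_sig) * np.random.default_rng(77).standard_normal(X.shape)
        np.testing.assert_array_equal(noisy, expected)

    def test_non_finite_snr_rejected(self, rng):
        with pytest.raises(ValueError, match="finite"):
            add_noise_at_snr(np.zeros((1, 1, 4)), np.inf, rng)

    def test_no_noise_entry_reproduces_clean_accuracy(self, trained_small):
        clean = dfcgn.evaluate(trained_small["model"], trained_small["test"]).accuracy
        sweep = dfcgn.snr_sweep(trained_small["model"], trained_small["test"],
                                [None], seed=0)
        assert sweep.accuracy.iloc[0] == clean

    def test_heavy_noise_degrades_accuracy(self, trained_small):
        sweep = dfcgn.snr_sweep(trained_small["model"], trained_small["test"],
                                [20.0, -10.0], seed=0, n_noise_seeds=5)
        assert sweep.accuracy.iloc[1] <= sweep.accuracy.iloc[0]


def test_baseline_table_structure_and_chance_floor(epochs_small):
    cfg = TrainConfig(optimizer="adam", lr=1e-3, lr_decay=0.9, epochs=8,
                      ft2_xi=1e-4, seed=4)
    table = dfcgn.baseline_compare(epochs_small, cfg)
    assert list(table.columns) == ["feature_learning", "handcrafted"]
    assert set(table.index) == {"KNN", "SVM", "MLP", "DFCGN"}
    assert ((table >= 0.0) & (table <= 1.0)).all().all()
    # classical learners resolve the easy fixture well above chance
    assert table.loc[["KNN", "SVM", "MLP"], "feature_learning"].min() > 0.55
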