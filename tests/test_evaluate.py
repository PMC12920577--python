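"""Folds, training, grid search, metrics, statistics and mitigation rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from graphecg.errors import ValidationError
from graphecg.evaluate import (ablation_run, auc_bruteforce, binary_counts_metrics,
                               compute_metrics, grid_search, make_folds,
                               mask_feature_subset, optimize_thresholds,
                               paired_t_test, patient_holdout, roc_auc_ovr,
                               temporal_alert_aggregation, train,
                               _veto_predictions)
from graphecg.model import ModelConfig

TINY_CFG = ModelConfig(n_gnn_layers=1, n_transformer_layers=1, d_model=8, heads=2,
                       d_gnn=4, head_hidden=6, dropout=0.0, learning_rate=1e-2,
                       batch_size=32)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

class TestFolds:
    def test_segment_level_partition(self):
        labels = np.repeat(np.arange(4), 25)
        split = make_folds(labels, k=5, level="segment", seed=0)
        all_idx = np.sort(np.concatenate(split.folds))
        np.testing.assert_array_equal(all_idx, np.arange(100))
        assert all(len(f) == 20 for f in split.folds)

    def test_patient_level_keeps_patients_whole(self):
        labels = np.zeros(40, dtype=int)
        pids = np.repeat([f"p{i}" for i in range(4)], 10)
        split = make_folds(labels, k=2, level="patient", seed=1, patient_ids=pids)
        for fold in split.folds:
            fold_pids = set(pids[fold])
            other = set(pids) - fold_pids
            assert not (fold_pids & other)

    def test_determinism(self):
        labels = np.repeat(np.arange(4), 10)
        a = make_folds(labels, 4, seed=3)
        b = make_folds(labels, 4, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_small_class_warns(self):
        labels = np.array([0] * 20 + [1] * 2)
        with pytest.warns(UserWarning):
            make_folds(labels, k=5)

    def test_patient_holdout_disjoint(self):
        pids = np.repeat([f"p{i}" for i in range(8)], 5)
        tr, te = patient_holdout(pids, 0.25, seed=2)
        assert not (set(pids[tr]) & set(pids[te]))
        assert len(tr) + len(te) == 40


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TestTrain:
    def test_separable_data_high_accuracy(self, cluster_features):
        """The classifier fits linearly separable 4-class clusters."""
        idx = np.arange(cluster_features.n_segments)
        result = train(cluster_features, idx, TINY_CFG, seed=0, max_epochs=20)
        assert result.history["train_acc"].iloc[-1] >= 0.95

    def test_deterministic_history(self, cluster_features):
        idx = np.arange(cluster_features.n_segments)
        h1 = train(cluster_features, idx, TINY_CFG, seed=5, max_epochs=3).history
        h2 = train(cluster_features, idx, TINY_CFG, seed=5, max_epochs=3).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_history_bounded_by_max_epochs(self, cluster_features):
        idx = np.arange(cluster_features.n_segments)
        result = train(cluster_features, idx, TINY_CFG, seed=0, max_epochs=1)
        assert len(result.history) == 1

    def test_empty_training_set_rejected(self, cluster_features):
        with pytest.raises(ValidationError):
            train(cluster_features, np.array([], dtype=int), TINY_CFG)


class TestGridSearch:
    def test_single_combination(self, cluster_features):
        folds = make_folds(cluster_features.labels, 2, seed=0)
        best, table = grid_search(cluster_features, {"learning_rate": [1e-2]},
                                  folds, base_config=TINY_CFG, max_epochs=2)
        assert best.learning_rate == 1e-2
        assert len(table) == 1

    def test_divergent_candidate_loses(self, cluster_features):
        """A wildly large learning rate must not win the search."""
        folds = make_folds(cluster_features.labels, 2, seed=0)
        best, table = grid_search(cluster_features,
                                  {"learning_rate": [1e-2, 10.0]},
                                  folds, base_config=TINY_CFG, max_epochs=3)
        assert best.learning_rate == 1e-2
        assert len(table) == 2

    def test_table_size_is_grid_product(self, cluster_features):
        folds = make_folds(cluster_features.labels, 2, seed=0)
        _, table = grid_search(cluster_features,
                               {"learning_rate": [1e-2, 1e-3], "d_gnn": [4, 8]},
                               folds, base_config=TINY_CFG, max_epochs=1)
        assert len(table) == 4


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_binary_counts_closed_form(self):
        m = binary_counts_metrics(tp=90, fn=10, fp=5, tn=95)
        assert m["sensitivity"] == pytest.approx(0.9, abs=1e-9)
        assert m["precision"] == pytest.approx(90 / 95, abs=1e-9)
        assert m["specificity"] == pytest.approx(0.95, abs=1e-9)
        assert m["accuracy"] == pytest.approx(0.925, abs=1e-9)
        assert m["f1"] == pytest.approx(0.9230769230769231, abs=1e-9)
        assert m["fnr"] == pytest.approx(0.1, abs=1e-9)
        assert m["fpr"] == pytest.approx(0.05, abs=1e-9)

    def test_confusion_matches_counts(self):
        """A dataset realizing TP=90/FN=10/FP=5/TN=95 reproduces the formulas."""
        y_true = np.array([1] * 100 + [0] * 100)
        y_pred = np.array([1] * 90 + [0] * 10 + [1] * 5 + [0] * 95)
        rep = compute_metrics(y_true, y_pred, n_classes=2, class_names=["neg", "pos"])
        row = rep.per_class.loc["pos"]
        ref = binary_counts_metrics(90, 10, 5, 95)
        for key in ("precision", "sensitivity", "specificity", "f1", "fnr", "fpr"):
            assert row[key] == pytest.approx(ref[key], abs=1e-9)
        assert rep.accuracy == pytest.approx(ref["accuracy"], abs=1e-9)

    def test_perfect_predictions(self):
        y = np.repeat(np.arange(4), 5)
        rep = compute_metrics(y, y, n_classes=4)
        assert rep.accuracy == 1.0
        assert (rep.per_class[["precision", "sensitivity", "f1"]] == 1.0).all().all()

    def test_micro_equals_accuracy(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        rep = compute_metrics(y_true, y_pred, n_classes=4)
        assert rep.micro["precision"] == rep.micro["sensitivity"] == rep.accuracy

    def test_fnr_fpr_complements(self):
        rng = np.random.default_rng(1)
        rep = compute_metrics(rng.integers(0, 3, 100), rng.integers(0, 3, 100), 3)
        for _, row in rep.per_class.iterrows():
            assert row["fnr"] + row["sensitivity"] == pytest.approx(1.0, abs=1e-12)
            assert row["fpr"] + row["specificity"] == pytest.approx(1.0, abs=1e-12)

    def test_absent_class_zeroed(self):
        rep = compute_metrics(np.array([0, 0, 1]), np.array([0, 0, 1]), n_classes=3)
        assert rep.per_class.iloc[2]["support"] == 0
        assert rep.per_class.iloc[2]["sensitivity"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.array([0, 1]), np.array([0]), 2)


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        auc = roc_auc_ovr(y, probs)
        assert auc["0"] == 1.0 and auc["1"] == 1.0

    def test_all_ties_half(self):
        y = np.array([0, 0, 1, 1])
        probs = np.full((4, 2), 0.5)
        assert roc_auc_ovr(y, probs)["1"] == pytest.approx(0.5)

    def test_hand_case_three_quarters(self):
        """Positives {0.9, 0.8} vs negatives {0.7, 0.85}: 3 of 4 pairs concordant."""
        y = np.array([1, 1, 0, 0])
        p1 = np.array([0.9, 0.8, 0.7, 0.85])
        probs = np.stack([1 - p1, p1], axis=1)
        assert roc_auc_ovr(y, probs)["1"] == pytest.approx(0.75, abs=1e-12)
        assert auc_bruteforce(np.array([0.9, 0.8]), np.array([0.7, 0.85])) == 0.75

    def test_rank_equals_bruteforce_and_sklearn(self):
        """Rank-statistic AUC matches pair counting and sklearn on small sets."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(10, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            probs = np.stack([1 - scores, scores], axis=1)
            mine = roc_auc_ovr(y, probs)["1"]
            brute = auc_bruteforce(scores[y == 1], scores[y == 0])
            skl = roc_auc_score(y, scores)
            assert mine == pytest.approx(brute, abs=1e-12)
            assert mine == pytest.approx(skl, abs=1e-12)

    def test_single_class_flagged(self):
        out = roc_auc_ovr(np.zeros(5, dtype=int), np.full((5, 2), 0.5))
        assert np.isnan(out["1"])


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t_test(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computation(self):
        a = np.array([0.98, 0.97, 0.99])
        b = np.array([0.95, 0.96, 0.94])
        t, df, p = paired_t_test(a, b)
        assert t == pytest.approx(0.03 / (0.02 / np.sqrt(3)), rel=1e-9)
        assert df == 2
        ref = sstats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(6), rng.random(6)
        t1, _, p1 = paired_t_test(a, b)
        t2, _, p2 = paired_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_nonzero_mean(self):
        with pytest.warns(UserWarning):
            t, _, p = paired_t_test(np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        assert np.isinf(t) and p == 0.0


# ---------------------------------------------------------------------------
# mitigation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def val_probs():
    rng = np.random.default_rng(8)
    n = 300
    y = rng.integers(0, 4, n)
    logits = rng.normal(size=(n, 4))
    logits[np.arange(n), y] += 1.5  # informative but imperfect
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs, y


class TestMitigation:
    def test_alert_example(self):
        assert temporal_alert_aggregation(["N", "V", "V", "N"], 2) == [(2, "V")]

    def test_k1_alerts_every_abnormal(self):
        stream = ["N", "V", "N", "S", "E", "N"]
        alerts = temporal_alert_aggregation(stream, 1)
        assert [i for i, _ in alerts] == [1, 3, 4]

    def test_all_normal_no_alerts(self):
        assert temporal_alert_aggregation(["N"] * 10, 2) == []

    def test_long_run_realerts_every_k(self):
        assert temporal_alert_aggregation(["V"] * 6, 3) == [(2, "V"), (5, "V")]

    def test_k_zero_rejected(self):
        with pytest.raises(ValidationError):
            temporal_alert_aggregation(["N"], 0)

    def test_fpr_monotone_in_threshold(self, val_probs):
        """Raising the V threshold never increases V-class FPR (full grid)."""
        probs, y = val_probs
        v_idx, n_idx = 3, 1  # alphabetical E N S V
        fprs = []
        for thr in np.arange(0.0, 1.0, 0.01):
            pred = _veto_predictions(probs, v_idx, thr, n_idx)
            rep = compute_metrics(y, pred, n_classes=4)
            fprs.append(rep.per_class.iloc[v_idx]["fpr"])
        assert all(b <= a + 1e-12 for a, b in zip(fprs, fprs[1:]))

    def test_zero_thresholds_reproduce_argmax(self, val_probs):
        probs, y = val_probs
        thr = optimize_thresholds(probs, y, "min_fpr_at_sensitivity",
                                  sensitivity_target=0.0)
        pred0 = _veto_predictions(probs, 3, thr["V"], 1)
        # target 0 is always feasible at every threshold, so the scan keeps
        # the highest threshold; with target impossible to violate the
        # argmax rule must be recovered at threshold 0
        base = np.argmax(probs, axis=1)
        pred_zero = _veto_predictions(probs, 3, 0.0, 1)
        np.testing.assert_array_equal(pred_zero, base)

    def test_separable_probs_reach_zero_fpr(self):
        """Perfectly separated validation scores allow FPR 0 at sensitivity 1."""
        y = np.array([1, 1, 1, 3, 3, 3])  # N and V
        probs = np.zeros((6, 4))
        probs[:3, 1] = 0.9
        probs[:3, 3] = 0.1
        probs[3:, 3] = 0.95
        probs[3:, 1] = 0.05
        thr = optimize_thresholds(probs, y, sensitivity_target=1.0)
        pred = _veto_predictions(probs, 3, thr["V"], 1)
        rep = compute_metrics(y, pred, n_classes=4)
        assert rep.per_class.iloc[3]["sensitivity"] == 1.0
        assert rep.per_class.iloc[3]["fpr"] == 0.0


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

class TestAblation:
    def test_single_variant_single_row(self, cluster_features):
        idx = np.arange(cluster_features.n_segments)
        table = ablation_run(cluster_features, idx[:120], idx[120:],
                             variants=("hybrid",), config=TINY_CFG, max_epochs=2)
        assert len(table) == 1 and table["variant"][0] == "hybrid"

    def test_feature_subset_masks_nonlinear_columns(self):
        from graphecg.features import FEATURE_NAMES, FeatureTensor
        import graphecg.evaluate as ev
        rng = np.random.default_rng(0)
        ft = FeatureTensor(values=rng.random((5, 3, 2, len(FEATURE_NAMES))),
                           mask=np.zeros((5, 3, 2, len(FEATURE_NAMES))),
                           labels=np.zeros(5, dtype=int))
        masked = mask_feature_subset(ft, "time_frequency")
        cols = list(ev.NONLINEAR_COLS)
        assert [FEATURE_NAMES[c] for c in cols] == ["apen", "sd1", "sd2"]
        np.testing.assert_array_equal(masked.values[..., cols], 0.0)
        np.testing.assert_array_equal(masked.mask[..., cols], 1.0)
        other = [i for i in range(len(FEATURE_NAMES)) if i not in cols]
        np.testing.assert_array_equal(masked.values[..., other], ft.values[..., other])

    def test_reproducible_table(self, cluster_features):
        idx = np.arange(cluster_features.n_segments)
        t1 = ablation_run(cluster_features, idx[:120], idx[120:],
                          variants=("hybrid", "gnn_only"), config=TINY_CFG, max_epochs=2)
        t2 = ablation_run(cluster_features, idx[:120], idx[120:],
                          variants=("hybrid", "gnn_only"), config=TINY_CFG, max_epochs=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_variant_rejected(self, cluster_features):
        idx = np.arange(cluster_features.n_segments)
        with pytest.raises(ValidationError):
            ablation_run(cluster_features, idx[:10], idx[10:], variants=("bogus",))
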