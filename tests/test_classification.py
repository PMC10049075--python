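import dataclasses

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ummetab.classification import (
    add_noise,
    bootstrap_auc,
    classification_report,
    derive_seed,
    loocv_classify,
    make_training_fold,
    oversample_balance,
    repeated_subsample_cv,
)
from ummetab.feature_io import ConfigurationError, PipelineConfig

FAST = PipelineConfig(master_seed=1, n_trees=40, oversample_n=60)


def _clusters(n_per, n_feat, gap, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, n_feat))
    X[:n_per, :] += gap
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


class TestOversample:
    def test_default_cohort_sizes_balanced(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(83, 5))
        y = np.array(["UM"] * 37 + ["control"] * 46)
        Xo, yo = oversample_balance(X, y, 200, seed=0)
        assert (yo == "UM").sum() == 200 and (yo == "control").sum() == 200

    def test_class_at_target_returned_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = np.array(["A"] * 5 + ["B"] * 5)
        Xo, yo = oversample_balance(X, y, 5, seed=0)
        a_rows = {tuple(r) for r in Xo[yo == "A"]}
        assert a_rows == {tuple(r) for r in X[:5]}

    def test_source_rows_preserved_as_set(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 4))
        y = np.array(["A"] * 4 + ["B"] * 8)
        Xo, yo = oversample_balance(X, y, 50, seed=3)
        for c in ("A", "B"):
            src = {tuple(r) for r in X[y == c]}
            out = {tuple(r) for r in Xo[yo == c]}
            assert out == src  # resampling adds no new rows, drops none

    def test_empty_class_impossible_and_oversized_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ConfigurationError):
            oversample_balance(X, np.array(["A"] * 5), n_target=3)


class TestAddNoise:
    def test_sd_zero_identity(self):
        X = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(add_noise(X, 0.0, 0), X)

    def test_empirical_sd_matches(self):
        X = np.zeros((500, 200))
        out = add_noise(X, 0.25, seed=5)
        assert (out - X).std() == pytest.approx(0.25, abs=0.01)
        assert (out - X).mean() == pytest.approx(0.0, abs=0.01)

    def test_deterministic_under_seed(self):
        X = np.ones((10, 10))
        np.testing.assert_array_equal(add_noise(X, 0.25, 7), add_noise(X, 0.25, 7))


class TestLOOCV:
    def test_separable_clusters_perfect(self):
        X, y = _clusters(8, 20, gap=10 * 0.25, seed=4)
        res = loocv_classify(X, y, FAST, positive_class="A")
        assert res.accuracy == 1.0
        assert res.auc_mean == 1.0 and res.auc_sd == 0.0

    def test_structural_contract(self):
        X, y = _clusters(5, 6, gap=1.0, seed=5)
        res = loocv_classify(X, y, FAST)
        assert res.probabilities.shape == (10, 2)
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert all(
            p == res.class_labels[int(np.argmax(row))]
            for p, row in zip(res.predictions, res.probabilities)
        )

    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ConfigurationError):
            loocv_classify(X, np.array(["A"] * 5), FAST)

    def test_deterministic_under_master_seed(self):
        X, y = _clusters(5, 8, gap=0.5, seed=6)
        a = loocv_classify(X, y, FAST)
        b = loocv_classify(X, y, FAST)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        assert a.predictions == b.predictions

    def test_training_fold_excludes_heldout_rows(self):
        """Fold boundary: oversampled/noised training data cannot contain
        the held-out sample (leakage guard)."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 5))
        y = np.array(["A"] * 6 + ["B"] * 6)
        cfg = dataclasses.replace(FAST, noise_sd=0.0)  # noise off to compare rows
        for i in (0, 7):
            holdout = np.zeros(12, dtype=bool)
            holdout[i] = True
            Xf, yf = make_training_fold(X, y, holdout, cfg, seed=13)
            assert not any(np.allclose(row, X[i]) for row in Xf)

    def test_replicate_group_leaves_fold_together(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 4))
        y = np.array(["A"] * 5 + ["B"] * 5)
        groups = np.array([0, 0, 1, 2, 3, 4, 5, 6, 7, 8])
        res = loocv_classify(X, y, FAST, groups=groups)
        assert res.probabilities.shape == (10, 2)


class TestBootstrapAUC:
    def test_perfect_scores(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        truth = np.array([0, 0, 1, 1])
        assert bootstrap_auc(scores, truth, 25, 0) == (1.0, 0.0)

    def test_constant_scores_tie_handling(self):
        scores = np.full(20, 0.5)
        truth = np.array([0, 1] * 10)
        mean, sd = bootstrap_auc(scores, truth, 25, 0)
        assert mean == 0.5 and sd == 0.0

    def test_matches_rank_oracle_on_shared_indices(self):
        rng = np.random.default_rng(11)
        scores = rng.random(40)
        truth = (rng.random(40) < 0.5).astype(int)
        n_boot = 25
        idx = [rng.integers(0, 40, size=40) for _ in range(n_boot)]
        # make sure each resample has both classes (redraw otherwise)
        idx = [
            i if len(set(truth[i])) == 2 else np.arange(40) for i in idx
        ]
        mean, sd = bootstrap_auc(scores, truth, n_boot, 0, indices=idx)

        def mw_auc(s, t):  # brute-force Mann-Whitney with half ties
            pos, neg = s[t == 1], s[t == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            return wins / (len(pos) * len(neg))

        oracle = [mw_auc(scores[i], truth[i]) for i in idx]
        assert mean == pytest.approx(np.mean(oracle), abs=1e-12)
        assert sd == pytest.approx(np.std(oracle, ddof=1), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ConfigurationError):
            bootstrap_auc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestRepeatedSubsample:
    def test_reduces_to_plain_loocv_at_full_fraction(self):
        X, y = _clusters(4, 5, gap=1.5, seed=12)
        cfg = dataclasses.replace(FAST, n_repeats=1, subsample_frac=1.0)
        summary = repeated_subsample_cv(X, y, cfg)
        rep_seed = derive_seed(cfg.master_seed, 3, 0)
        direct = loocv_classify(X, y, dataclasses.replace(cfg, master_seed=rep_seed))
        np.testing.assert_array_equal(
            summary.per_repeat[0].probabilities, direct.probabilities
        )

    def test_repeats_draw_different_subsamples(self):
        X, y = _clusters(8, 5, gap=1.0, seed=13)
        cfg = dataclasses.replace(FAST, n_repeats=3, subsample_frac=0.5)
        summary = repeated_subsample_cv(X, y, cfg)
        id_sets = [tuple(r.sample_ids) for r in summary.per_repeat]
        assert len(set(id_sets)) > 1
        assert len(summary.per_repeat) == 3
        for r in summary.per_repeat:
            assert len(r.sample_ids) == 8  # ceil(0.5 * 8) per class

    def test_too_small_class_rejected(self):
        X, y = _clusters(2, 3, gap=1.0)
        cfg = dataclasses.replace(FAST, n_repeats=1, subsample_frac=0.5)
        with pytest.raises(ConfigurationError):
            repeated_subsample_cv(X, y, cfg)


class TestReport:
    def _result(self, truth, preds, classes):
        from ummetab.classification import CVResult, _score_predictions

        per_class, acc = _score_predictions(truth, preds, classes)
        n = len(truth)
        proba = np.zeros((n, len(classes)))
        for i, p in enumerate(preds):
            proba[i, classes.index(p)] = 1.0
        return CVResult(
            sample_ids=[f"s{i}" for i in range(n)],
            class_labels=classes,
            probabilities=proba,
            predictions=preds,
            truth=truth,
            per_class=per_class,
            accuracy=acc,
            roc=None,
            auc_mean=None,
            auc_sd=None,
            positive_class=None,
            config_echo={},
            seed=0,
        )

    def test_all_correct(self):
        res = self._result(["A", "B"] * 3, ["A", "B"] * 3, ["A", "B"])
        df = classification_report(res)
        assert (df[["precision", "recall", "f1"]].to_numpy() == 1.0).all()
        assert df.attrs["accuracy"] == 1.0

    def test_never_predicted_class_zero_convention(self):
        res = self._result(["A", "A", "B"], ["A", "A", "A"], ["A", "B"])
        df = classification_report(res)
        assert df.loc["B", "precision"] == 0.0
        assert df.loc["B", "f1"] == 0.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(14)
        classes = ["A", "B", "C"]
        truth = [classes[i] for i in rng.integers(0, 3, 60)]
        preds = [classes[i] for i in rng.integers(0, 3, 60)]
        df = classification_report(self._result(truth, preds, classes))
        for c in classes:
            tp = sum(1 for t, p in zip(truth, preds) if t == c and p == c)
            fp = sum(1 for t, p in zip(truth, preds) if t != c and p == c)
            fn = sum(1 for t, p in zip(truth, preds) if t == c and p != c)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert df.loc[c, "precision"] == pytest.approx(prec)
            assert df.loc[c, "recall"] == pytest.approx(rec)
            assert df.loc[c, "f1"] == pytest.approx(f1)
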