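"""Oversampled, noise-regularized random-forest LOOCV validation.

Cohorts in this setting are small and imbalanced, so the validation engine
combines four ingredients:

* leave-one-out cross-validation — each sample is scored by a forest
  trained on all the others;
* per-fold oversampling with replacement so every class contributes the
  same number of training rows (200 by default);
* additive Gaussian training noise, N(0, 0.25 sd), as regularization;
* a 150-tree random forest with maximum depth 100.

Oversampling and noise are applied strictly inside each training fold.
Applying them before splitting would copy (noisy versions of) the held-out
sample into its own training set and inflate every metric; the leakage-free
ordering is the default and the only one used by the pipeline.

Held-out class-probability rows feed ROC curves, and the AUC is summarised
as mean +/- sd over 25 bootstrap resamples of the (score, label) pairs.
Robustness is assessed by repeating the whole LOOCV ten times on random
50% subsamples of every class.

All randomness descends from one master seed through
``numpy.random.SeedSequence`` spawning, so per-fold, per-repeat and
per-bootstrap streams are independent but fully reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score, roc_curve

from .feature_io import ConfigurationError, PipelineConfig


@dataclass
class CVResult:
    """Leave-one-out validation result for one task on one table."""

    sample_ids: list[str]
    class_labels: list[str]
    probabilities: np.ndarray  # (n_samples, n_classes), rows sum to 1
    predictions: list[str]
    truth: list[str]
    per_class: dict[str, dict[str, float]]  # precision/recall/f1/support
    accuracy: float
    roc: list[tuple[float, float]] | None  # (fpr, tpr); binary tasks only
    auc_mean: float | None
    auc_sd: float | None
    positive_class: str | None
    config_echo: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "class_labels": self.class_labels,
            "probabilities": self.probabilities.tolist(),
            "predictions": self.predictions,
            "truth": self.truth,
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "roc": self.roc,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "positive_class": self.positive_class,
            "config_echo": self.config_echo,
            "seed": self.seed,
        }


@dataclass
class RepeatSummary:
    """Ten-repeat 50%-subsample robustness summary."""

    per_repeat: list[CVResult]
    auc_range: tuple[float, float] | None
    f1_ranges: dict[str, tuple[float, float]]


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and a key path."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)


def oversample_balance(
    X: np.ndarray,
    y: np.ndarray,
    n_target: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample with replacement so each class has exactly ``n_target`` rows.

    Every original row of a class appears at least once (classes never
    exceed ``n_target`` here), topped up with uniform resampling. Rows are
    ordered class-by-class (sorted label order).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if any((y == c).sum() == 0 for c in classes):
        raise ConfigurationError("every class needs at least one sample")
    Xs, ys = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_target:
            raise ConfigurationError(
                f"class {c!r} has {len(idx)} samples, more than n_target={n_target}"
            )
        extra = rng.choice(idx, size=n_target - len(idx), replace=True)
        take = np.concatenate([idx, extra])
        Xs.append(X[take])
        ys.append(np.full(n_target, c, dtype=y.dtype))
    return np.vstack(Xs), np.concatenate(ys)


def add_noise(
    X: np.ndarray, sd: float = 0.25, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Return ``X`` plus i.i.d. Gaussian noise with standard deviation ``sd``."""
    if sd < 0:
        raise ConfigurationError("noise sd must be >= 0")
    if sd == 0:
        return X.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return X + rng.normal(0.0, sd, size=X.shape)


def make_training_fold(
    X: np.ndarray,
    y: np.ndarray,
    holdout: np.ndarray,
    cfg: PipelineConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the oversampled + noised training set excluding ``holdout``.

    ``holdout`` is a boolean mask of samples left out of this fold.
    Exposed separately so the fold boundary (no held-out information in
    training) can be inspected directly.
    """
    rng = np.random.default_rng(seed)
    Xt, yt = X[~holdout], np.asarray(y)[~holdout]
    if len(np.unique(yt)) < 2:
        raise ConfigurationError("training fold lost all but one class")
    Xo, yo = oversample_balance(Xt, yt, cfg.oversample_n, rng)
    return add_noise(Xo, cfg.noise_sd, rng), yo


def loocv_classify(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig,
    sample_ids: list[str] | None = None,
    positive_class: str | None = None,
    groups: np.ndarray | None = None,
) -> CVResult:
    """Leave-one-out cross-validation of the oversampled/noised forest.

    ``groups``, when given, defines fold-exclusion groups: all samples
    sharing a group id (e.g. technical replicates of one subject) leave
    the training set together with the held-out sample. For binary tasks
    the ROC curve and bootstrap AUC are computed over the positive-class
    probabilities; ``positive_class`` defaults to ``"UM"`` if present,
    else the last class in sorted order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ConfigurationError("need at least 3 samples for LOOCV")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ConfigurationError("need at least 2 classes")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)

    proba = np.zeros((n, len(classes)))
    for i in range(n):
        fold_seed = derive_seed(cfg.master_seed, 0, i)
        holdout = groups == groups[i]
        Xf, yf = make_training_fold(X, y, holdout, cfg, fold_seed)
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            random_state=derive_seed(cfg.master_seed, 1, i),
            n_jobs=1,
        )
        clf.fit(Xf, yf)
        p = clf.predict_proba(X[i : i + 1])[0]
        # align to the global class order (a singleton class can be absent
        # from its own training fold)
        for k, c in enumerate(clf.classes_.tolist()):
            proba[i, classes.index(c)] = p[k]

    predictions = [classes[int(np.argmax(row))] for row in proba]
    per_class, accuracy = _score_predictions(list(y), predictions, classes)

    roc = None
    auc_mean = auc_sd = None
    pos = None
    if len(classes) == 2:
        pos = positive_class or ("UM" if "UM" in classes else classes[-1])
        if pos not in classes:
            raise ConfigurationError(f"positive class {pos!r} not among {classes}")
        scores = proba[:, classes.index(pos)]
        truth_bin = (y == pos).astype(int)
        fpr, tpr, _ = roc_curve(truth_bin, scores)
        roc = list(zip(fpr.tolist(), tpr.tolist()))
        auc_mean, auc_sd = bootstrap_auc(
            scores, truth_bin, cfg.n_boot, derive_seed(cfg.master_seed, 2)
        )

    return CVResult(
        sample_ids=list(sample_ids),
        class_labels=classes,
        probabilities=proba,
        predictions=predictions,
        truth=[str(v) for v in y],
        per_class=per_class,
        accuracy=accuracy,
        roc=roc,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        positive_class=pos,
        config_echo=cfg.to_dict(),
        seed=cfg.master_seed,
    )


def bootstrap_auc(
    scores: np.ndarray,
    truth: np.ndarray,
    n_boot: int = 25,
    seed: int = 0,
    indices: list[np.ndarray] | None = None,
) -> tuple[float, float]:
    """Mean and sd of the ROC AUC over bootstrap resamples.

    Pairs ``(score, label)`` are resampled with replacement; resamples
    lacking one of the classes are redrawn. AUC uses the rank
    (Mann-Whitney) formulation with ties counted as half. ``indices`` may
    supply pre-drawn resample index arrays (e.g. for oracle comparisons).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ConfigurationError("bootstrap_auc needs both classes in truth")
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = []
    draws = 0
    while len(aucs) < n_boot:
        if indices is not None:
            idx = indices[len(aucs)]
        else:
            idx = rng.integers(0, n, size=n)
            draws += 1
            if draws > 1000 * n_boot:  # pragma: no cover - pathological labels
                raise ConfigurationError("could not draw resamples with both classes")
        t = truth[idx]
        if t.min() == t.max():
            if indices is not None:
                raise ConfigurationError("supplied resample lacks a class")
            continue
        aucs.append(roc_auc_score(t, scores[idx]))
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if n_boot > 1 else 0.0
    return mean, sd


def repeated_subsample_cv(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig,
    sample_ids: list[str] | None = None,
    positive_class: str | None = None,
) -> RepeatSummary:
    """Repeat LOOCV ``cfg.n_repeats`` times on per-class random subsamples.

    Each repeat draws ``ceil(frac * n_c)`` samples per class without
    replacement under a repeat-specific derived seed, then runs
    :func:`loocv_classify` with that seed as its master. With
    ``subsample_frac=1`` and one repeat this reduces exactly to a plain
    LOOCV under the derived seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    classes = sorted(np.unique(y).tolist())
    results: list[CVResult] = []
    for r in range(cfg.n_repeats):
        rep_seed = derive_seed(cfg.master_seed, 3, r)
        rng = np.random.default_rng(rep_seed)
        take: list[int] = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            k = math.ceil(cfg.subsample_frac * len(idx))
            if k < 2:
                raise ConfigurationError(
                    f"class {c!r} would have {k} < 2 samples after subsampling"
                )
            take.extend(rng.choice(idx, size=k, replace=False).tolist())
        take = sorted(take)
        cfg_r = dataclasses.replace(cfg, master_seed=rep_seed)
        results.append(
            loocv_classify(
                X[take],
                y[take],
                cfg_r,
                sample_ids=[sample_ids[i] for i in take],
                positive_class=positive_class,
            )
        )
    aucs = [r.auc_mean for r in results if r.auc_mean is not None]
    auc_range = (min(aucs), max(aucs)) if aucs else None
    f1_ranges = {
        c: (
            min(r.per_class[c]["f1"] for r in results),
            max(r.per_class[c]["f1"] for r in results),
        )
        for c in classes
    }
    return RepeatSummary(per_repeat=results, auc_range=auc_range, f1_ranges=f1_ranges)


def classification_report(result: CVResult):
    """Per-class precision/recall/F1/support plus accuracy, as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "class": c,
            "precision": result.per_class[c]["precision"],
            "recall": result.per_class[c]["recall"],
            "f1": result.per_class[c]["f1"],
            "support": result.per_class[c]["support"],
        }
        for c in result.class_labels
    ]
    df = pd.DataFrame(rows).set_index("class")
    df.attrs["accuracy"] = result.accuracy
    return df


def _score_predictions(
    truth: list, predictions: list, classes: list[str]
) -> tuple[dict[str, dict[str, float]], float]:
    p, r, f1, support = precision_recall_fscore_support(
        truth, predictions, labels=classes, zero_division=0
    )
    per_class = {
        c: {
            "precision": float(p[k]),
            "recall": float(r[k]),
            "f1": float(f1[k]),
            "support": int(support[k]),
        }
        for k, c in enumerate(classes)
    }
    accuracy = float(np.mean(np.asarray(truth) == np.asarray(predictions)))
    return per_class, accuracy
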