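"""Internal-standard PC-regression normalization and its quality metrics.

Spiked internal standards are present in every sample at fixed
concentration, so any systematic variation of their measured abundances is
technical. The normalization summarises that variation by the first two
principal components of the internal-standard matrix (samples as
observations) and removes, per feature, the component of abundance that a
linear regression on those two PC score vectors explains:

    normalized = abundance - fitted(PC1, PC2) + feature mean

Only well-detected features are corrected (more than ``nonzero_frac`` of
samples above zero); sparser features pass through with their original
log-transformed abundance. Samples whose per-feature |Z-score| exceeds
``z_outlier`` are excluded from the fit but still corrected with the
fitted coefficients. The regression is a Bayesian ridge (data-driven
regularization); with negligible regularization it coincides with
ordinary least squares.

Four diagnostics judge the result: the WTR score (pooled within-batch over
total variance, approaching 1 when batch variation is gone), mean pairwise
correlation of QC-sample profiles, and cross-validated balanced accuracies
of predicting batch labels and QC-versus-study labels from the features
(both should fall to chance after a successful correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import BayesianRidge
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .feature_io import (
    ConfigurationError,
    FeatureTable,
    SampleMetadata,
    SchemaError,
    StandardSet,
    StateError,
)


@dataclass
class NormalizationModel:
    """First two internal-standard PCs plus per-feature regression state."""

    sample_ids: list[str]
    standard_ids: list[str]
    pc_scores: np.ndarray  # (n_samples, 2) regressors
    pc_loadings: np.ndarray  # (n_internal, 2)
    explained_variance: np.ndarray  # fractions, length 2
    degenerate: bool = False
    coefficients: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    excluded_samples: dict[str, list[str]] = field(default_factory=dict)


def fit_standard_pcs(table: FeatureTable, standards: StandardSet) -> NormalizationModel:
    """PCA of the internal-standard matrix across samples.

    Each internal-standard row is centered (no scaling: standards are
    spiked at fixed concentration, so their scales are comparable) and the
    first two sample-score vectors are extracted by SVD. Sign convention:
    the largest-magnitude entry of each score vector is positive. If the
    standards carry no variance at all the model is flagged degenerate and
    the scores are zero.
    """
    if table.transform_state != "log1":
        raise StateError("fit_standard_pcs expects a log1-state table")
    standards.check_in_table(table)
    internal = sorted(standards.internal)
    if len(internal) < 2:
        raise ConfigurationError("need at least 2 internal standards")
    if table.n_samples < 3:
        raise ConfigurationError("need at least 3 samples to fit standard PCs")
    idx = [table.feature_index(f) for f in internal]
    M = table.abundances[idx, :]  # (n_internal, n_samples)
    centered = M - M.mean(axis=1, keepdims=True)
    n = table.n_samples
    if np.allclose(centered, 0.0):
        return NormalizationModel(
            sample_ids=list(table.sample_ids),
            standard_ids=internal,
            pc_scores=np.zeros((n, 2)),
            pc_loadings=np.zeros((len(internal), 2)),
            explained_variance=np.zeros(2),
            degenerate=True,
        )
    # observations = samples, variables = internal standards
    D = centered.T  # (n_samples, n_internal)
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    k = min(2, S.size)
    scores = np.zeros((n, 2))
    loadings = np.zeros((len(internal), 2))
    scores[:, :k] = U[:, :k] * S[:k]
    loadings[:, :k] = Vt[:k, :].T
    total_var = float((S**2).sum())
    explained = np.zeros(2)
    explained[:k] = (S[:k] ** 2) / total_var if total_var > 0 else 0.0
    for c in range(2):
        j = int(np.argmax(np.abs(scores[:, c])))
        if scores[j, c] < 0:
            scores[:, c] *= -1
            loadings[:, c] *= -1
    return NormalizationModel(
        sample_ids=list(table.sample_ids),
        standard_ids=internal,
        pc_scores=scores,
        pc_loadings=loadings,
        explained_variance=explained,
    )


def normalize_pc_regression(
    table: FeatureTable,
    model: NormalizationModel,
    nonzero_frac: float = 0.75,
    z_outlier: float = 3.0,
) -> tuple[FeatureTable, NormalizationModel]:
    """Regress each well-detected feature on the standard PCs and keep
    the residual plus the feature mean.

    Eligibility: strictly more than ``nonzero_frac * n_samples`` entries
    above zero. For eligible features, samples with per-feature
    |Z-score| > ``z_outlier`` are excluded from fitting but corrected like
    all others. Ineligible features are returned bitwise unchanged. A
    degenerate (zero-variance) model leaves the whole table unchanged.
    """
    if table.transform_state != "log1":
        raise StateError("normalize_pc_regression expects a log1-state table")
    if list(table.sample_ids) != list(model.sample_ids):
        raise SchemaError("model was fitted on different samples than the table")
    out = table.abundances.copy()
    model.coefficients = {}
    model.excluded_samples = {}
    if model.degenerate:
        return table.with_state(out, "log1"), model
    X = model.pc_scores
    n = table.n_samples
    eligible_count = nonzero_frac * n
    for i, fid in enumerate(table.feature_ids):
        y = table.abundances[i, :]
        if (y > 0).sum() <= eligible_count:
            continue
        sd = y.std(ddof=0)
        if sd == 0:
            continue
        z = (y - y.mean()) / sd
        include = np.abs(z) <= z_outlier
        reg = BayesianRidge()
        reg.fit(X[include], y[include])
        fitted = reg.predict(X)
        out[i, :] = y - fitted + y.mean()
        model.coefficients[fid] = (
            float(reg.intercept_),
            float(reg.coef_[0]),
            float(reg.coef_[1]),
        )
        model.excluded_samples[fid] = [
            s for s, inc in zip(table.sample_ids, include) if not inc
        ]
    return table.with_state(out, "log1"), model


@dataclass
class NormalizationMetrics:
    """Diagnostics of batch-variation removal; ``None`` marks a metric
    whose preconditions (two batches, >= 2 QC samples) are not met."""

    wtr: float | None
    qc_correlation: float | None
    batch_prediction_score: float | None
    qc_prediction_score: float | None

    def to_dict(self) -> dict:
        return {
            "wtr": self.wtr,
            "qc_correlation": self.qc_correlation,
            "batch_prediction_score": self.batch_prediction_score,
            "qc_prediction_score": self.qc_prediction_score,
        }


def compute_metrics(
    table: FeatureTable, meta: SampleMetadata, seed: int = 0
) -> NormalizationMetrics:
    """WTR score, QC correlations and the two prediction scores.

    WTR is the mean over features of pooled within-batch variance divided
    by total variance (1 = no between-batch variance). Prediction scores
    are stratified 5-fold cross-validated balanced accuracies of a default
    random forest predicting batch (study samples) or QC-versus-study
    labels; chance level is 0.5.
    """
    X = table.abundances.T  # samples x features
    batches = meta.column("batch", table.sample_ids)
    roles = meta.column("role", table.sample_ids)
    is_qc = roles == "qc"
    is_study = roles == "study"

    wtr = None
    batch_score = None
    study_batches = batches[is_study]
    if len(np.unique(study_batches)) >= 2:
        wtr = _wtr_score(table.abundances[:, is_study], study_batches)
        batch_score = _prediction_score(X[is_study], study_batches, seed)

    qc_corr = None
    qc_score = None
    if is_qc.sum() >= 2:
        qc_corr = _mean_pairwise_correlation(table.abundances[:, is_qc])
        if is_study.sum() >= 2:
            labels = np.where(is_qc, "qc", "study")[is_qc | is_study]
            qc_score = _prediction_score(X[is_qc | is_study], labels, seed + 1)

    return NormalizationMetrics(
        wtr=wtr,
        qc_correlation=qc_corr,
        batch_prediction_score=batch_score,
        qc_prediction_score=qc_score,
    )


def _wtr_score(abundances: np.ndarray, batches: np.ndarray) -> float:
    """Mean over features of (pooled within-batch SS) / (total SS)."""
    total = ((abundances - abundances.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    within = np.zeros_like(total)
    for b in np.unique(batches):
        sub = abundances[:, batches == b]
        within += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ok = total > 0
    if not ok.any():
        return 1.0
    return float((within[ok] / total[ok]).mean())


def _mean_pairwise_correlation(qc_profiles: np.ndarray) -> float:
    """Mean Pearson correlation over all QC sample pairs (columns)."""
    c = np.corrcoef(qc_profiles.T)
    iu = np.triu_indices_from(c, k=1)
    return float(np.nanmean(c[iu]))


def _prediction_score(X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Stratified 5-fold CV balanced accuracy of a default random forest."""
    classes, counts = np.unique(y, return_counts=True)
    n_splits = int(min(5, counts.min()))
    if n_splits < 2:
        return float("nan")
    clf = RandomForestClassifier(random_state=seed % 2**31, n_jobs=1)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="balanced_accuracy")
    return float(scores.mean())
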