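"""Unsupervised (PCA, t-SNE) and supervised (PLS-DA) sample embeddings.

PCA and t-SNE explore whether groups separate without supervision; PLS-DA
projects samples onto latent directions that maximise covariance between
feature abundance and (one-hot) class membership. PLS-DA separates groups
very easily, so it is used here for visualisation only — cross-validated
classification, not the embedding, carries the inferential weight.

Per-group 95% confidence ellipses are drawn from the sample mean and
covariance of the embedded coordinates scaled by the chi-square(2 df)
quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .feature_io import ConfigurationError, DegenerateDataError, FeatureTable, StateError


@dataclass
class GroupEllipse:
    """Confidence ellipse of one group in a 2-D embedding."""

    center: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2)
    radii: np.ndarray  # semi-axis lengths, descending
    orientation: np.ndarray  # (2, 2) columns = axis directions
    confidence_level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: Mahalanobis distance inside the chi-square bound."""
        d = points - self.center
        inv = np.linalg.pinv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return m2 <= stats.chi2.ppf(self.confidence_level, df=2)


@dataclass
class Embedding:
    """Sample coordinates from one embedding method."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    method: str  # pca | tsne | plsda
    explained_variance: np.ndarray | None = None
    group_ellipses: dict[str, GroupEllipse] | None = None


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| entry of each column > 0."""
    out = scores.copy()
    for c in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, c])))
        if out[j, c] < 0:
            out[:, c] *= -1
    return out


def pca_embedding(table: FeatureTable, k: int = 2) -> Embedding:
    """Top-k principal-component scores of the samples."""
    if table.transform_state != "z":
        raise StateError("pca_embedding expects a z-state table")
    if not 2 <= k <= 3:
        raise ConfigurationError("k must be 2 or 3")
    X = table.abundances.T
    if k > min(X.shape):
        raise ConfigurationError(f"k={k} exceeds min(n_samples, n_features)")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return Embedding(
        sample_ids=list(table.sample_ids),
        coordinates=_fix_signs(scores),
        method="pca",
        explained_variance=pca.explained_variance_ratio_.copy(),
    )


def tsne_embedding(
    table: FeatureTable, seed: int = 0, perplexity: float = 30.0
) -> Embedding:
    """2-D t-SNE of the samples; reproducible under a fixed seed.

    Purely for visual exploration: no geometric guarantees beyond shape
    and determinism are made (or tested) for this method.
    """
    if table.transform_state != "z":
        raise StateError("tsne_embedding expects a z-state table")
    n = table.n_samples
    if n <= 3 * perplexity:
        raise ConfigurationError(
            f"perplexity {perplexity} too large for {n} samples (need n > 3*perplexity)"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed % 2**31,
        init="pca",
        max_iter=500,
    )
    coords = ts.fit_transform(table.abundances.T)
    return Embedding(
        sample_ids=list(table.sample_ids),
        coordinates=np.asarray(coords, dtype=float),
        method="tsne",
    )


def plsda_embedding(table: FeatureTable, y: np.ndarray, k: int = 2) -> Embedding:
    """PLS-DA scores: PLS2 regression of one-hot class labels on features.

    The first latent direction maximises covariance between the feature
    projection and the label projection; per-component explained variance
    of the feature block is reported.
    """
    if table.transform_state != "z":
        raise StateError("plsda_embedding expects a z-state table")
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ConfigurationError("PLS-DA needs at least 2 classes")
    X = table.abundances.T
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[y == c, j] = 1.0
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, Y)
    scores = np.asarray(pls.x_scores_, dtype=float)
    total = float((X - X.mean(axis=0)).var(axis=0, ddof=0).sum())
    expl = None
    if total > 0:
        # variance of X captured by each deflated component
        load = np.asarray(pls.x_loadings_)
        expl = np.array(
            [
                float(scores[:, c].var(ddof=0) * (load[:, c] ** 2).sum() / total)
                for c in range(k)
            ]
        )
    return Embedding(
        sample_ids=list(table.sample_ids),
        coordinates=_fix_signs(scores),
        method="plsda",
        explained_variance=expl,
    )


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> GroupEllipse:
    """Ellipse from the sample mean/covariance scaled by the chi2(2) quantile.

    Semi-axis lengths are ``sqrt(eigenvalue * chi2.ppf(level, 2))``; for
    points on a line the minor axis has zero width.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ConfigurationError("confidence_ellipse expects (m, 2) coordinates")
    if points.shape[0] < 3:
        raise DegenerateDataError("need at least 3 points for an ellipse")
    center = points.mean(axis=0)
    cov = np.cov(points.T, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    return GroupEllipse(
        center=center,
        covariance=cov,
        radii=np.sqrt(vals * q),
        orientation=vecs,
        confidence_level=level,
    )


def add_group_ellipses(
    emb: Embedding, labels: np.ndarray, level: float = 0.95
) -> Embedding:
    """Attach per-group confidence ellipses (first two coordinates)."""
    labels = np.asarray(labels)
    ellipses = {}
    for g in sorted(np.unique(labels).tolist()):
        pts = emb.coordinates[labels == g][:, :2]
        if pts.shape[0] >= 3:
            ellipses[str(g)] = confidence_ellipse(pts, level)
    emb.group_ellipses = ellipses
    return emb
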