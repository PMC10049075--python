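"""Transformations, feature-inclusion filtering and batch merging.

The inclusion rule works on ``log(1 + x)`` abundances: all strictly
positive values of a table are pooled across features and samples, the 2nd
percentile of that pool (linear-interpolation definition) becomes the
detection threshold, and a feature is kept when at least 5 samples exceed
the threshold. The threshold is computed per ion mode and per batch on the
table being filtered; merged analyses keep only features detected in both
batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_io import (
    DegenerateDataError,
    FeatureTable,
    SchemaError,
    StandardSet,
    StateError,
)


def log_transform(table: FeatureTable) -> FeatureTable:
    """Replace every raw entry x by natural log(1 + x)."""
    if table.transform_state != "raw":
        raise StateError(
            f"log_transform expects a raw table, got {table.transform_state!r}"
        )
    return table.with_state(np.log1p(table.abundances), "log1")


def pooled_detection_threshold(table: FeatureTable, percentile: float = 2.0) -> float:
    """Percentile of the pooled multiset of strictly positive entries.

    Zeros encode below-detection and are excluded from the pool. Uses the
    linear-interpolation percentile definition.
    """
    if table.transform_state != "log1":
        raise StateError("pooled_detection_threshold expects a log1-state table")
    pool = table.abundances[table.abundances > 0]
    if pool.size == 0:
        raise DegenerateDataError("no non-zero entries to pool")
    return float(np.percentile(pool, percentile, method="linear"))


def filter_features(
    table: FeatureTable,
    threshold: float,
    min_samples: int = 5,
    standards: StandardSet | None = None,
) -> FeatureTable:
    """Keep features with >= ``min_samples`` entries strictly above ``threshold``.

    Row order is preserved and the operation is idempotent at a fixed
    threshold. Standard features, when given, are exempt from removal:
    they must survive filtering to anchor normalization.
    """
    if table.transform_state != "log1":
        raise StateError("filter_features expects a log1-state table")
    counts = (table.abundances > threshold).sum(axis=1)
    keep = counts >= min_samples
    if standards is not None:
        protected = np.array([f in standards.all_ids for f in table.feature_ids])
        keep |= protected
    return table.select_features(keep)


def merge_batches(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Concatenate two batches, keeping features detected in both.

    The feature set is the id intersection (in ``a``'s row order, with
    ``a``'s m/z and retention times); samples are concatenated ``a`` then
    ``b``. Both tables must share the ion mode and transform state and
    have disjoint sample sets.
    """
    if a.ion_mode != b.ion_mode:
        raise SchemaError(f"ion-mode mismatch: {a.ion_mode!r} vs {b.ion_mode!r}")
    if a.transform_state != b.transform_state:
        raise SchemaError(
            f"transform-state mismatch: {a.transform_state!r} vs {b.transform_state!r}"
        )
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise SchemaError(f"batches share samples: {sorted(overlap)}")
    common = set(a.feature_ids) & set(b.feature_ids)
    a_sub = a.select_features(common)
    b_sub = b.select_features(common)
    # align b's rows to a's order
    b_order = {f: i for i, f in enumerate(b_sub.feature_ids)}
    idx = [b_order[f] for f in a_sub.feature_ids]
    merged = np.hstack([a_sub.abundances, b_sub.abundances[idx, :]])
    return FeatureTable(
        feature_ids=a_sub.feature_ids,
        mz=a_sub.mz,
        rt=a_sub.rt,
        ion_mode=a.ion_mode,
        abundances=merged,
        sample_ids=a_sub.sample_ids + b_sub.sample_ids,
        transform_state=a.transform_state,
    )


def z_transform(table: FeatureTable) -> FeatureTable:
    """Standardise each feature row to mean 0, population sd 1.

    Constant rows map to all-zeros. Idempotent: applying it to an already
    z-state table returns the same values.
    """
    if table.transform_state not in ("log1", "z"):
        raise StateError("z_transform expects a log1- or z-state table")
    x = table.abundances
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return table.with_state(z, "z")


@dataclass(frozen=True)
class FilterReport:
    """Provenance of one filtering pass."""

    n_features_in: int
    threshold: float
    percentile: float
    min_samples: int
    n_features_out: int


def filter_with_report(
    table: FeatureTable,
    percentile: float = 2.0,
    min_samples: int = 5,
    standards: StandardSet | None = None,
) -> tuple[FeatureTable, FilterReport]:
    """Threshold + filter in one step, returning a provenance report."""
    thr = pooled_detection_threshold(table, percentile)
    out = filter_features(table, thr, min_samples, standards)
    return out, FilterReport(
        n_features_in=table.n_features,
        threshold=thr,
        percentile=percentile,
        min_samples=min_samples,
        n_features_out=out.n_features,
    )
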