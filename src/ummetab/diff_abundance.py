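"""Per-feature differential-abundance screen.

For every feature: a Welch two-sample t-test of UM versus control
abundance, a Pearson correlation with longest tumor diameter (LTD, mm)
over UM samples, Benjamini-Hochberg adjustment of both p-value families,
and a joint flag for features significant on both axes — the pattern that
would mark a feature as genuinely tumor-associated. A p-value histogram
diagnostic checks the expected shape (a left-tail spike of true signals
over a uniform null background); its uniformity statistic is a chi-square
over the right-tail bins (p > 0.2), which a well-calibrated null should
pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import (
    ConfigurationError,
    FeatureTable,
    SampleMetadata,
    ValidationError,
)


@dataclass
class DiffAbundanceResult:
    """Per-feature screen results; ``frame`` has one row per feature with
    columns t_stat, p_t, q_t, r_ltd, p_r, q_r, degenerate_t, joint_flag."""

    frame: pd.DataFrame
    alpha: float

    def flagged_features(self) -> list[str]:
        return self.frame.index[self.frame["joint_flag"]].tolist()


def feature_t_tests(
    table: FeatureTable, meta: SampleMetadata, equal_var: bool = False
) -> pd.DataFrame:
    """Two-sided two-sample t-test (Welch by default) per feature, UM vs control.

    QC/blank/replicate samples are excluded. A feature whose two groups
    both have zero variance gets p = 1 and a ``degenerate`` flag rather
    than an error.
    """
    if table.transform_state == "raw":
        raise ValidationError("run the t-tests on transformed abundances")
    study = [
        s
        for s in table.sample_ids
        if meta.frame.loc[s, "role"] == "study"
    ]
    groups = meta.column("group", study)
    sub = table.select_samples(study)
    um = sub.abundances[:, groups == "UM"]
    ctrl = sub.abundances[:, groups == "control"]
    if um.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ConfigurationError("need >= 2 samples per group for t-tests")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(um, ctrl, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"t_stat": t, "p_t": p, "degenerate_t": degenerate},
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


def ltd_correlation(table: FeatureTable, meta: SampleMetadata) -> pd.DataFrame:
    """Pearson correlation of each feature with LTD over UM study samples.

    Two-sided p-values come from the t transform of r with n - 2 degrees
    of freedom. Requires at least 3 UM samples with a recorded LTD.
    """
    if table.transform_state == "raw":
        raise ValidationError("run correlations on transformed abundances")
    df = meta.frame
    usable = [
        s
        for s in table.sample_ids
        if df.loc[s, "role"] == "study"
        and df.loc[s, "group"] == "UM"
        and pd.notna(pd.to_numeric(df.loc[s, "ltd"], errors="coerce"))
    ]
    if len(usable) < 3:
        raise ConfigurationError("need >= 3 UM samples with LTD")
    ltd = pd.to_numeric(df.loc[usable, "ltd"]).to_numpy(dtype=float)
    X = table.select_samples(usable).abundances
    n = len(usable)
    xc = X - X.mean(axis=1, keepdims=True)
    lc = ltd - ltd.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (lc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ lc) / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    return pd.DataFrame(
        {"r_ltd": r, "p_r": p},
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    """Bonferroni familywise adjustment (the conservative alternative)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return np.minimum(p * p.size, 1.0)


def pvalue_histogram_diagnostic(
    p: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, float, float]:
    """Histogram counts plus a chi-square uniformity check of the right tail.

    Returns ``(counts, statistic, p_uniform)`` where the statistic tests
    the bins with left edge > 0.2 against a flat profile. True signals
    concentrate near zero, so a healthy p-value distribution spikes in the
    first bins while the right tail stays uniform.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    tail = counts[edges[:-1] > 0.2 - 1e-12]
    if tail.sum() == 0:
        return counts, float("inf"), 0.0
    expected = np.full(tail.size, tail.sum() / tail.size)
    stat, p_unif = stats.chisquare(tail, expected)
    return counts, float(stat), float(p_unif)


def diff_abundance_screen(
    table: FeatureTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
    equal_var: bool = False,
    correction: str = "bh",
) -> DiffAbundanceResult:
    """Run the full screen: t-tests, LTD correlations, adjustment, joint flag."""
    adjust = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}[correction]
    tt = feature_t_tests(table, meta, equal_var=equal_var)
    rr = ltd_correlation(table, meta)
    frame = tt.join(rr)
    frame["q_t"] = adjust(np.clip(frame["p_t"].to_numpy(), np.finfo(float).tiny, 1.0))
    frame["q_r"] = adjust(np.clip(frame["p_r"].to_numpy(), np.finfo(float).tiny, 1.0))
    frame["joint_flag"] = (frame["q_t"] <= alpha) & (frame["q_r"] <= alpha)
    return DiffAbundanceResult(frame=frame, alpha=alpha)


def joint_significance(res: DiffAbundanceResult, alpha: float | None = None) -> list[str]:
    """Features significant on both axes after adjustment (nested in alpha)."""
    a = res.alpha if alpha is None else alpha
    f = res.frame
    mask = (f["q_t"] <= a) & (f["q_r"] <= a)
    return f.index[mask].tolist()
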