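import numpy as np
import pytest

from conftest import make_metadata, make_table
from ummetab.feature_io import ConfigurationError, SchemaError, StandardSet, StateError
from ummetab.normalization import (
    compute_metrics,
    fit_standard_pcs,
    normalize_pc_regression,
)
from ummetab.qc_filter import log_transform
from ummetab.synthetic_data import (
    SimulationConfig,
    share_exact_stress_config,
    simulate_cohort,
)


def _std_table(std_rows, extra_rows=0, seed=0):
    """Table whose first rows are internal standards."""
    rng = np.random.default_rng(seed)
    n_std, n_samples = std_rows.shape
    vals = np.vstack([std_rows, rng.normal(5, 1, size=(extra_rows, n_samples))])
    t = make_table(vals, state="log1")
    std = StandardSet(internal=set(t.feature_ids[:n_std]))
    return t, std


class TestFitStandardPCs:
    def test_constant_standards_degenerate(self):
        t, std = _std_table(np.full((3, 6), 2.0))
        model = fit_standard_pcs(t, std)
        assert model.degenerate
        np.testing.assert_array_equal(model.pc_scores, 0.0)

    def test_rank_one_standards_recover_profile(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 12))
        t, std = _std_table(np.vstack([5 + x, 7 + x]))
        model = fit_standard_pcs(t, std)
        pc1 = model.pc_scores[:, 0]
        # PC1 proportional to the shared profile, PC2 negligible
        corr = np.corrcoef(pc1, x)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        assert np.abs(model.pc_scores[:, 1]).max() < 1e-10
        assert model.explained_variance[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        M = rng.normal(6, 1, size=(8, 20))
        t, std = _std_table(M)
        model = fit_standard_pcs(t, std)
        # independent oracle: eigenvectors of the sample covariance of the
        # centered standard matrix (samples as observations)
        D = (M - M.mean(axis=1, keepdims=True)).T
        C = D.T @ D
        vals, vecs = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1]
        for c in range(2):
            expected = D @ vecs[:, order[c]]
            j = int(np.argmax(np.abs(expected)))
            if expected[j] < 0:
                expected = -expected
            np.testing.assert_allclose(model.pc_scores[:, c], expected, atol=1e-8)

    def test_invariant_to_standard_ordering(self):
        rng = np.random.default_rng(6)
        M = rng.normal(6, 1, size=(5, 15))
        t, std = _std_table(M)
        model_a = fit_standard_pcs(t, std)
        perm = [3, 1, 4, 0, 2]
        t2 = make_table(M[perm], state="log1",
                        feature_ids=[t.feature_ids[i] for i in perm])
        model_b = fit_standard_pcs(t2, StandardSet(internal=set(t2.feature_ids)))
        np.testing.assert_allclose(model_a.pc_scores, model_b.pc_scores, atol=1e-10)

    def test_too_few_standards_rejected(self):
        t = make_table(np.ones((5, 4)), state="log1")
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_internal=1)
        with pytest.raises(ConfigurationError, match="3 samples"):
            small = make_table(np.ones((3, 2)), state="log1")
            fit_standard_pcs(small, StandardSet(internal=set(small.feature_ids[:2])))

    def test_requires_log_state(self):
        t = make_table(np.ones((3, 5)))
        with pytest.raises(StateError):
            fit_standard_pcs(t, StandardSet(internal=set(t.feature_ids[:2])))


class TestNormalizePCRegression:
    def test_degenerate_model_is_identity(self):
        t, std = _std_table(np.full((3, 8), 2.0), extra_rows=4)
        model = fit_standard_pcs(t, std)
        out, _ = normalize_pc_regression(t, model)
        np.testing.assert_array_equal(out.abundances, t.abundances)

    def test_perfect_linear_feature_flattens_to_mean(self):
        rng = np.random.default_rng(7)
        M = rng.normal(6, 1, size=(4, 30))
        t, std = _std_table(M, extra_rows=2)
        model = fit_standard_pcs(t, std)
        i = 5
        t.abundances[i, :] = 3.0 + 0.8 * model.pc_scores[:, 0]
        out, _ = normalize_pc_regression(t, model)
        row = out.abundances[i]
        np.testing.assert_allclose(row, row.mean(), atol=1e-8)
        assert row.mean() == pytest.approx(t.abundances[i].mean(), abs=1e-10)

    def test_bayesian_ridge_matches_ols_at_high_snr(self):
        """Contract: with informative data the data-driven regularization
        is negligible and the fit coincides with ordinary least squares."""
        rng = np.random.default_rng(8)
        M = rng.normal(6, 1, size=(5, 60))
        t, std = _std_table(M, extra_rows=1)
        model = fit_standard_pcs(t, std)
        X = model.pc_scores
        beta = np.array([0.7, -0.4])
        t.abundances[5, :] = 4.0 + X @ beta + rng.normal(0, 0.01, size=60)
        out, model = normalize_pc_regression(t, model)
        fid = t.feature_ids[5]
        coef = np.array(model.coefficients[fid][1:])
        A = np.column_stack([np.ones(60), X])
        ols = np.linalg.lstsq(A, t.abundances[5], rcond=None)[0]
        np.testing.assert_allclose(coef, ols[1:], atol=1e-3)

    def test_ineligible_features_pass_through_bitwise(self):
        rng = np.random.default_rng(9)
        M = rng.normal(6, 1, size=(3, 20))
        t, std = _std_table(M, extra_rows=3)
        sparse = 4
        t.abundances[sparse, :] = 0.0
        t.abundances[sparse, :5] = rng.normal(6, 1, size=5)  # 25% non-zero
        before = t.abundances[sparse].copy()
        out, model = normalize_pc_regression(t, model=fit_standard_pcs(t, std))
        np.testing.assert_array_equal(out.abundances[sparse], before)
        assert t.feature_ids[sparse] not in model.coefficients

    def test_outliers_excluded_from_fit_but_corrected(self):
        rng = np.random.default_rng(10)
        M = rng.normal(6, 0.5, size=(4, 40))
        t, std = _std_table(M, extra_rows=1)
        model = fit_standard_pcs(t, std)
        t.abundances[4, :] = 5.0 + 0.3 * model.pc_scores[:, 0]
        t.abundances[4, 0] = 60.0  # gross outlier
        out, model = normalize_pc_regression(t, model)
        fid = t.feature_ids[4]
        assert t.sample_ids[0] in model.excluded_samples[fid]
        # outlier still corrected: its value changed by the fitted term
        assert out.abundances[4, 0] != t.abundances[4, 0]

    def test_sample_mismatch_raises(self):
        t, std = _std_table(np.random.default_rng(1).normal(6, 1, (3, 10)))
        model = fit_standard_pcs(t, std)
        other = t.select_samples(t.sample_ids[:5])
        with pytest.raises(SchemaError):
            normalize_pc_regression(other, model)

    def test_share_exact_batch_effect_removed(self):
        """On the share_exact stress cohort the batch-mean differences of
        eligible features shrink by an order of magnitude."""
        cfg = share_exact_stress_config(seed=2, n_features=60)
        pos, _, meta, std = simulate_cohort(cfg)
        log = log_transform(pos)
        model = fit_standard_pcs(log, std)
        norm, model = normalize_pc_regression(log, model)
        batch = meta.column("batch", log.sample_ids)
        d, r = batch == "discovery", batch == "replication"
        bio = [i for i, f in enumerate(log.feature_ids)
               if f in model.coefficients and f not in std.all_ids]
        before = np.abs(log.abundances[bio][:, r].mean(1)
                        - log.abundances[bio][:, d].mean(1)).mean()
        after = np.abs(norm.abundances[bio][:, r].mean(1)
                       - norm.abundances[bio][:, d].mean(1)).mean()
        assert after <= 0.1 * before


class TestMetrics:
    def _cohort(self, batch_sd, seed):
        cfg = SimulationConfig(
            n_discovery={"control": 20, "BAP1": 10, "SF3B1": 0, "EIF1AX": 0},
            n_replication={"control": 10, "BAP1": 10, "SF3B1": 0, "EIF1AX": 0},
            n_features=60,
            n_informative=0,
            effect_size=0.0,
            batch_effect_sd=batch_sd,
            dropout_rate=0.0,
            n_qc=3,
            seed=seed,
        )
        pos, _, meta, _ = simulate_cohort(cfg)
        return log_transform(pos), meta

    def test_null_batches_look_alike(self):
        log, meta = self._cohort(batch_sd=0.0, seed=13)
        m = compute_metrics(log, meta, seed=0)
        assert m.wtr > 0.95
        assert abs(m.batch_prediction_score - 0.5) < 0.15

    def test_large_batch_offset_is_predictable(self):
        log, meta = self._cohort(batch_sd=2.0, seed=14)
        m = compute_metrics(log, meta, seed=0)
        assert m.batch_prediction_score >= 0.9
        assert m.wtr < 0.8

    def test_duplicated_qc_profiles_give_unit_correlation(self):
        t = make_table(np.tile(np.arange(10.0)[:, None], (1, 4)), state="log1")
        meta = make_metadata(t.sample_ids, roles=["qc"] * 4)
        m = compute_metrics(t, meta, seed=0)
        assert m.qc_correlation == pytest.approx(1.0)

    def test_single_batch_metrics_absent(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.normal(5, 1, (10, 8)), state="log1")
        meta = make_metadata(t.sample_ids)  # all discovery
        m = compute_metrics(t, meta, seed=0)
        assert m.wtr is None and m.batch_prediction_score is None
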