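"""QC filtering, PQN, kNN imputation, glog and PCA, each against an oracle."""

import numpy as np
import pandas as pd
import pytest

from metabmd.preprocessing import (QcFilterThresholds, apply_coefficients,
                                   glog_transform, knn_impute,
                                   optimize_lambda, pca_overview,
                                   pqn_normalize, qc_filter)


def random_qc_table(table_factory, n_feat=300, seed=0):
    """Random table with QCs and blanks, and planted per-rule violations."""
    rng = np.random.default_rng(seed)
    n_study, n_qc, n_blank = 17, 8, 3
    n = n_study + n_qc + n_blank
    X = rng.lognormal(10, 1, (n_feat, n))
    # plant violations
    for i in range(0, n_feat, 7):       # missing in QCs
        X[i, n_study:n_study + rng.integers(1, n_qc)] = np.nan
    for i in range(1, n_feat, 11):      # unstable in QCs
        X[i, n_study:n_study + n_qc] *= rng.lognormal(0, 0.8, n_qc)
    for i in range(2, n_feat, 5):       # blank contamination
        X[i, n_study + n_qc:] = X[i, :n_study].mean() * 0.6
    for i in range(3, n_feat, 13):      # sparse in study samples
        X[i, :rng.integers(9, 15)] = np.nan
    roles = ["study"] * n_study + ["qc"] * n_qc + ["blank"] * n_blank
    doses = [0, 0, 0, 55, 55, 55, 110, 110, 110, 220, 220, 220, 441, 441,
             881, 881, 881] + [None] * (n_qc + n_blank)
    return table_factory(X, roles, doses=doses)


def qc_filter_oracle(table, th=QcFilterThresholds()):
    """Feature-by-feature literal re-evaluation of the four rules."""
    keep = []
    qc_ids = table.sample_ids("qc")
    blank_ids = table.sample_ids("blank")
    study_ids = table.sample_ids("study")
    for fid in table.intensities.index:
        row = table.intensities.loc[fid]
        present = lambda s: pd.notna(row[s]) and row[s] > 0
        qc_frac = 100.0 * sum(present(s) for s in qc_ids) / len(qc_ids)
        qc_vals = [row[s] for s in qc_ids if present(s)]
        if len(qc_vals) >= 2 and np.mean(qc_vals) > 0:
            rsd = 100.0 * np.std(qc_vals, ddof=1) / np.mean(qc_vals)
        else:
            rsd = np.inf
        blank_mean = np.mean([row[s] if pd.notna(row[s]) else 0.0
                              for s in blank_ids])
        qc_mean = np.mean([row[s] if pd.notna(row[s]) else 0.0 for s in qc_ids])
        ratio = 100.0 * blank_mean / qc_mean if qc_mean > 0 else np.inf
        st_frac = 100.0 * sum(present(s) for s in study_ids) / len(study_ids)
        ok = (qc_frac > th.qc_presence_min and rsd < th.qc_rsd_max
              and ratio < th.blank_ratio_max and st_frac > th.study_presence_min)
        if ok:
            keep.append(fid)
    return keep


class TestQcFilter:
    def test_clean_feature_retained_with_margin(self, table_factory):
        X = np.concatenate([
            np.full(17, 1000.0),                       # study, all present
            1000 * (1 + 0.05 * np.arange(-4, 4) / 4),  # QCs, RSD ~ 4%
            np.full(3, 1.0),                           # blanks ~ 0.1%
        ]).reshape(1, -1)
        t = table_factory(X, ["study"] * 17 + ["qc"] * 8 + ["blank"] * 3,
                          doses=[0] * 3 + [55] * 3 + [110] * 3 + [220] * 3
                                + [441] * 2 + [881] * 3 + [None] * 11)
        kept, report = qc_filter(t)
        assert kept.n_features == 1
        assert report.table.iloc[0]["retained"]

    def test_rsd_exactly_30_percent_rejected(self, table_factory):
        # QC values engineered to an RSD of exactly 30%: the rule is strict <
        spread = 30.0 / np.sqrt(2.0)
        qc = np.array([100.0 - spread, 100.0 + spread])
        assert np.std(qc, ddof=1) / np.mean(qc) == pytest.approx(0.3)
        X = np.concatenate([np.full(17, 100.0), qc, [0.1]]).reshape(1, -1)
        t = table_factory(X, ["study"] * 17 + ["qc"] * 2 + ["blank"],
                          doses=[0] * 3 + [55] * 3 + [110] * 3 + [220] * 3
                                + [441] * 2 + [881] * 3 + [None] * 3)
        kept, report = qc_filter(t)
        assert kept.n_features == 0
        assert report.table.iloc[0]["qc_rsd_pct"] == pytest.approx(30.0)
        assert not report.table.iloc[0]["pass_qc_rsd"]

    def test_matches_brute_force_oracle_on_random_fixture(self, table_factory):
        t = random_qc_table(table_factory, n_feat=400, seed=3)
        kept, report = qc_filter(t)
        assert sorted(kept.intensities.index) == sorted(qc_filter_oracle(t))

    def test_result_independent_of_feature_order(self, table_factory):
        t = random_qc_table(table_factory, n_feat=60, seed=4)
        perm = np.random.default_rng(0).permutation(t.intensities.index)
        t_perm = t.subset_features(perm)
        kept1, _ = qc_filter(t)
        kept2, _ = qc_filter(t_perm)
        assert sorted(kept1.intensities.index) == sorted(kept2.intensities.index)

    def test_refuses_qc_rules_without_qc_samples(self, table_factory):
        t = table_factory(np.ones((2, 17)), ["study"] * 17,
                          doses=[0] * 3 + [55] * 3 + [110] * 3 + [220] * 3
                                + [441] * 2 + [881] * 3)
        with pytest.raises(ValueError, match="QC"):
            qc_filter(t)


class TestPqn:
    def _study_table(self, table_factory, X):
        n = X.shape[1]
        doses = ([0] * 3 + [55] * 3 + [110] * 3 + [220] * 3 + [441] * 2
                 + [881] * 3)[:n]
        return table_factory(X, ["study"] * n, doses=doses)

    def test_doubled_sample_has_doubled_coefficient(self, table_factory):
        # dilution invariance: a sample duplicated at twice the intensity
        # gets exactly twice the quotient coefficient and an identical
        # normalized profile
        rng = np.random.default_rng(2)
        base = rng.lognormal(5, 1, (50, 1))
        X = np.hstack([base, base * rng.lognormal(0, 0.05, (50, 3)), 2.0 * base])
        t = self._study_table(table_factory, X)
        normalized, coeffs = pqn_normalize(t)
        assert coeffs.iloc[-1] == pytest.approx(2.0 * coeffs.iloc[0], rel=1e-12)
        assert normalized.intensities.iloc[:, -1].to_numpy() == pytest.approx(
            normalized.intensities.iloc[:, 0].to_numpy(), rel=1e-12)

    def test_single_feature_coefficient_is_plain_ratio(self, table_factory):
        X = np.array([[10.0, 20.0, 40.0, 5.0]])
        t = self._study_table(table_factory, X)
        _, coeffs = pqn_normalize(t, min_shared=1)
        ref = np.median(X)  # per-feature median over study samples
        assert coeffs.to_numpy() == pytest.approx(X[0] / ref)

    def test_matches_median_quotient_oracle(self, table_factory):
        rng = np.random.default_rng(7)
        X = rng.lognormal(6, 1, (50, 17))
        X[rng.random((50, 17)) < 0.05] = np.nan
        t = self._study_table(table_factory, X)
        _, coeffs = pqn_normalize(t)
        ref = np.nanmedian(np.where(X > 0, X, np.nan), axis=1)
        for j, sid in enumerate(t.intensities.columns):
            q = X[:, j] / ref
            mask = ~np.isnan(X[:, j]) & (X[:, j] > 0) & ~np.isnan(ref) & (ref > 0)
            assert coeffs[sid] == pytest.approx(np.median(q[mask]), rel=1e-12)

    def test_invariant_to_reference_scaling(self, table_factory):
        # scaling the whole matrix (hence the reference profile) leaves the
        # quotient coefficients unchanged
        rng = np.random.default_rng(8)
        X = rng.lognormal(6, 1, (40, 17))
        t = self._study_table(table_factory, X)
        n1, c1 = pqn_normalize(t)
        t2 = self._study_table(table_factory, 2.0 * X)
        n2, c2 = pqn_normalize(t2)
        assert c2.to_numpy() == pytest.approx(c1.to_numpy(), rel=1e-12)
        assert n2.intensities.to_numpy() == pytest.approx(
            2.0 * n1.intensities.to_numpy(), rel=1e-12)

    def test_apply_coefficients_identity_halving_and_missing(self, table_factory):
        X = np.arange(1.0, 13.0).reshape(3, 4)
        t = self._study_table(table_factory, X)
        sids = list(t.intensities.columns)
        ones = pd.Series(1.0, index=sids)
        pd.testing.assert_frame_equal(
            apply_coefficients(t, ones).intensities, t.intensities)
        half = ones.copy()
        half.iloc[1] = 2.0
        out = apply_coefficients(t, half)
        assert out.intensities.iloc[:, 1].to_numpy() == pytest.approx(X[:, 1] / 2)
        with pytest.raises(ValueError, match=sids[0]):
            apply_coefficients(t, ones.drop(sids[0]))


def knn_oracle(table, k):
    """Exhaustive pairwise-distance kNN imputation, written independently."""
    X = table.intensities.to_numpy(float)
    fids = list(table.intensities.index)
    out = X.copy()
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            if not np.isnan(X[i, j]):
                continue
            cands = []
            for m in range(X.shape[0]):
                if m == i or np.isnan(X[m, j]):
                    continue
                both = ~np.isnan(X[i]) & ~np.isnan(X[m])
                if not both.any():
                    continue
                d = np.sqrt(np.mean((X[i, both] - X[m, both]) ** 2))
                cands.append((d, fids[m], m))
            if not cands:
                out[i, j] = np.nanmean(X[i])
                continue
            cands.sort()
            out[i, j] = np.mean([X[m, j] for _, _, m in cands[:k]])
    return out


class TestKnnImpute:
    def test_zero_distance_neighbor_copied_at_k1(self, table_factory):
        A = np.array([5.0, 7.0, 9.0, 11.0])
        B = A.copy()
        B[2] = np.nan
        t = table_factory(np.vstack([A, B]), ["study"] * 4,
                          doses=[0, 55, 110, 220])
        out = knn_impute(t, k=1)
        assert out.intensities.iloc[1, 2] == A[2]

    def test_no_missing_is_identity(self, table_factory):
        X = np.random.default_rng(0).uniform(1, 9, (6, 5))
        t = table_factory(X, ["study"] * 5, doses=[0, 55, 110, 220, 441])
        pd.testing.assert_frame_equal(knn_impute(t).intensities, t.intensities)

    def test_observed_values_never_altered(self, table_factory):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 9, (30, 17))
        X[rng.random(X.shape) < 0.08] = np.nan
        t = table_factory(X, ["study"] * 17,
                          doses=[0] * 3 + [55] * 3 + [110] * 3 + [220] * 3
                                + [441] * 2 + [881] * 3)
        out = knn_impute(t, k=5).intensities.to_numpy()
        obs = ~np.isnan(X)
        assert out[obs] == pytest.approx(X[obs])
        assert not np.isnan(out).any()

    def test_matches_exhaustive_oracle(self, table_factory):
        rng = np.random.default_rng(9)
        X = rng.lognormal(3, 1, (100, 17))
        X[rng.random(X.shape) < 0.05] = np.nan
        t = table_factory(X, ["study"] * 17,
                          doses=[0] * 3 + [55] * 3 + [110] * 3 + [220] * 3
                                + [441] * 2 + [881] * 3)
        out = knn_impute(t, k=5).intensities.to_numpy()
        assert out == pytest.approx(knn_oracle(t, 5), rel=1e-10, nan_ok=True)

    def test_all_missing_feature_refused(self, table_factory):
        X = np.ones((2, 4))
        X[0] = np.nan
        t = table_factory(X, ["study"] * 4, doses=[0, 55, 110, 220])
        with pytest.raises(ValueError, match="missing in all"):
            knn_impute(t)


class TestGlog:
    def test_small_lambda_limit_is_natural_log(self, table_factory):
        X = np.array([[1.0, 10.0, 1000.0]])
        t = table_factory(X, ["study"] * 3, doses=[0, 55, 110])
        out = glog_transform(t, lam=1e-12).intensities.to_numpy()
        assert out == pytest.approx(np.log(X), abs=1e-6)

    def test_zero_maps_to_log_half_sqrt_lambda(self, table_factory):
        t = table_factory(np.array([[0.0, 4.0]]), ["study"] * 2, doses=[0, 55])
        out = glog_transform(t, lam=9.0).intensities.to_numpy()
        assert out[0, 0] == pytest.approx(np.log(np.sqrt(9.0) / 2.0))

    def test_strictly_increasing_preserves_order(self, table_factory):
        x = np.sort(np.random.default_rng(0).uniform(0, 100, 20))
        t = table_factory(x.reshape(1, -1), ["study"] * 20, doses=[0] * 5 + [55] * 15)
        out = glog_transform(t, lam=50.0).intensities.to_numpy().ravel()
        assert (np.diff(out) > 0).all()

    def test_optimized_lambda_beats_unit_lambda(self, table_factory):
        from metabmd.preprocessing import _qc_variance_spread
        rng = np.random.default_rng(4)
        base = rng.lognormal(4, 2, 60)
        qc = base[:, None] * rng.lognormal(0, 0.15, (60, 8))
        study = base[:, None] * rng.lognormal(0, 0.3, (60, 17))
        t = table_factory(np.hstack([study, qc]),
                          ["study"] * 17 + ["qc"] * 8,
                          doses=[0] * 3 + [55] * 3 + [110] * 3 + [220] * 3
                                + [441] * 2 + [881] * 3 + [None] * 8)
        lam = optimize_lambda(t, grid_points=60)
        qc_ids = t.sample_ids("qc")
        assert _qc_variance_spread(t, lam, qc_ids) <= \
            _qc_variance_spread(t, 1.0, qc_ids)

    def test_optimize_refuses_without_qcs(self, table_factory):
        t = table_factory(np.ones((3, 4)), ["study"] * 4, doses=[0, 55, 110, 220])
        with pytest.raises(ValueError, match="QC"):
            optimize_lambda(t)


class TestPca:
    def test_identical_samples_identical_scores(self, table_factory):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 1, 10)
        X = np.column_stack([col, col, rng.uniform(0, 1, 10)])
        t = table_factory(X, ["study"] * 3, doses=[0, 55, 110])
        scores, _ = pca_overview(t, 2)
        assert scores.iloc[0].to_numpy() == pytest.approx(scores.iloc[1].to_numpy())

    def test_rank_one_matrix_fully_explained_by_pc1(self, table_factory):
        v = np.arange(1.0, 6.0)
        X = np.outer(v, [1.0, 2.0, 3.0])
        t = table_factory(X, ["study"] * 3, doses=[0, 55, 110])
        _, ev = pca_overview(t, 1)
        assert ev.iloc[0] == pytest.approx(100.0)

    def test_scores_match_svd_oracle_up_to_sign(self, table_factory):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 9, (20, 8))
        t = table_factory(X, ["study"] * 8,
                          doses=[0, 0, 55, 110, 220, 441, 881, 881])
        scores, _ = pca_overview(t, 3)
        C = X.T - X.T.mean(axis=0)
        U, S, Vt = np.linalg.svd(C, full_matrices=False)
        oracle = U[:, :3] * S[:3]
        for j in range(3):
            got = scores.iloc[:, j].to_numpy()
            assert min(np.abs(got - oracle[:, j]).max(),
                       np.abs(got + oracle[:, j]).max()) < 1e-8
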