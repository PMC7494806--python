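"""Correlations, standardized PCA and Ward clustering against oracles."""

import numpy as np
import pandas as pd
import pytest

from droughtmem._errors import ComputationError
from droughtmem.multivariate import (ClusterResult, cluster_summary,
                                     correlation_matrix, pca, select_components,
                                     ward_cluster)


def _frame(arr, prefix="v"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in
                                      range(arr.shape[1])],
                        index=[f"A{i:03d}" for i in range(arr.shape[0])])


class TestCorrelation:
    def test_self_and_exact_anticorrelation(self):
        x = np.arange(20.0)
        df = _frame(np.column_stack([x, x, -x]))
        r, _, _ = correlation_matrix(df)
        assert r.loc["v0", "v1"] == pytest.approx(1.0)
        assert r.loc["v0", "v2"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        df = _frame(rng.normal(size=(20, 2)))
        r, p, _ = correlation_matrix(df)
        a, b = df["v0"].to_numpy(), df["v1"].to_numpy()
        ac, bc = a - a.mean(), b - b.mean()
        oracle = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert abs(r.loc["v0", "v1"] - oracle) < 1e-10
        assert r.equals(r.T)
        assert (r.abs() <= 1 + 1e-12).all().all()

    def test_significance_stars(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        df = _frame(np.column_stack([x, x + rng.normal(0, 0.1, 60),
                                     rng.normal(size=60)]))
        _, p, stars = correlation_matrix(df)
        assert stars.loc["v0", "v1"] == "**"
        assert p.loc["v0", "v1"] < 0.01


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(0, 1, 30)
        df = _frame(np.column_stack([t, 2 * t, -t]))
        res = pca(df)
        assert res.cumulative_variance[0] == pytest.approx(1.0)

    def test_two_variable_closed_form(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=200)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.normal(size=200)
        df = _frame(np.column_stack([a, b]))
        r = np.corrcoef(a, b)[0, 1]
        res = pca(df)
        assert res.eigenvalues == pytest.approx([1 + r, 1 - r], abs=1e-10)

    def test_orthonormal_loadings_and_svd_oracle(self):
        rng = np.random.default_rng(7)
        df = _frame(rng.normal(size=(30, 6)))
        res = pca(df)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-10)
        assert res.eigenvalues.sum() == pytest.approx(6.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        # SVD oracle on the standardized matrix
        Z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        sv = np.linalg.svd(Z, compute_uv=False)
        assert np.allclose(sorted(sv**2 / (len(df) - 1), reverse=True),
                           res.eigenvalues, atol=1e-8)
        # sign convention: dominant loading of each component is positive
        for c in range(6):
            assert L[np.argmax(np.abs(L[:, c])), c] > 0


def _blobs(seed=8, n_per=12, spread=0.2):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [8, 0], [0, 8]])
    pts = np.vstack([c + rng.normal(0, spread, (n_per, 2)) for c in centers])
    truth = np.repeat([0, 1, 2], n_per)
    return _frame(pts, prefix="pc"), truth, centers


class TestWard:
    def test_k_equals_n_gives_singletons(self):
        df, _, _ = _blobs(n_per=2)
        res = ward_cluster(df, k=len(df))
        assert res.labels.nunique() == len(df)

    def test_recovers_separated_blobs(self):
        df, truth, centers = _blobs()
        res = ward_cluster(df, k=3)
        # oracle: nearest true center assignment
        oracle = np.argmin(((df.to_numpy()[:, None, :] - centers) ** 2)
                           .sum(-1), axis=1)
        for cid in res.labels.unique():
            members = oracle[res.labels.to_numpy() == cid]
            assert len(set(members)) == 1  # perfect up to relabeling
        assert (oracle == truth).all()

    def test_row_permutation_invariance(self):
        df, _, _ = _blobs(seed=9)
        res = ward_cluster(df, k=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(df))
        res_p = ward_cluster(df.iloc[perm], k=3)
        # identical partition up to relabeling
        joined = pd.crosstab(res.labels, res_p.labels.reindex(res.labels.index))
        assert (joined.astype(bool).sum(axis=1) == 1).all()

    def test_k_larger_than_n_raises(self):
        df, _, _ = _blobs(n_per=2)
        with pytest.raises(ComputationError):
            ward_cluster(df, k=len(df) + 1)

    def test_matches_sklearn_agglomerative(self):
        # independent implementation cross-check
        sklearn = pytest.importorskip("sklearn.cluster")
        df, _, _ = _blobs(seed=10, spread=1.0)
        res = ward_cluster(df, k=3)
        ref = sklearn.AgglomerativeClustering(n_clusters=3,
                                              linkage="ward").fit(df.to_numpy())
        joined = pd.crosstab(res.labels.to_numpy(), ref.labels_)
        assert (joined.astype(bool).sum(axis=1) == 1).all()


class TestClusterSummary:
    def test_groupby_oracle_and_singleton_se(self):
        rng = np.random.default_rng(11)
        feats = _frame(rng.normal(size=(10, 2)))
        feats.columns = ["RCI", "PCI"]
        labels = pd.Series([1] * 9 + [2], index=feats.index, name="cluster")
        res = ClusterResult(labels=labels, k=2, linkage=np.empty((0, 4)),
                            n_components_used=2)
        table = cluster_summary(res, feats)
        big = feats.iloc[:9]
        row = table.set_index("cluster").loc[1]
        assert row["RCI_mean"] == pytest.approx(big["RCI"].mean())
        assert row["RCI_se"] == pytest.approx(big["RCI"].std(ddof=1) / 3.0)
        assert np.isnan(table.set_index("cluster").loc[2, "RCI_se"])

    def test_identical_rows_have_zero_se(self):
        feats = pd.DataFrame({"RCI": [4.0] * 5, "PCI": [6.0] * 5},
                             index=[f"A{i}" for i in range(5)])
        labels = pd.Series([1] * 5, index=feats.index, name="cluster")
        res = ClusterResult(labels=labels, k=1, linkage=np.empty((0, 4)),
                            n_components_used=2)
        table = cluster_summary(res, feats)
        assert table.loc[0, "RCI_se"] == 0.0


def test_select_components_covers_variance_threshold():
    rng = np.random.default_rng(12)
    df = _frame(rng.normal(size=(40, 6)))
    res = pca(df)
    scores = select_components(res, 0.70)
    m = scores.shape[1]
    assert res.cumulative_variance[m - 1] >= 0.70
    assert m == 1 or res.cumulative_variance[m - 2] < 0.70
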