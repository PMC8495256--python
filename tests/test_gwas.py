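import numpy as np
import pandas as pd
import pytest
from scipy import stats

from introgmap.gwas import (
    MixedLMAssociation,
    StructureModel,
    _null_delta,
    grm_vanraden,
    mlm_scan,
    pca_structure,
    permutation_threshold,
    summarize_scan,
)

from conftest import make_marker_set


def random_marker_set(seed, n=60, m=30, p=None):
    rng = np.random.default_rng(seed)
    if p is None:
        p = rng.uniform(0.15, 0.85, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(float)
    # guard against monomorphic draws
    mono = (calls.std(axis=0) == 0)
    calls[0, mono] = np.abs(calls[0, mono] - 1)
    return make_marker_set(calls)


def full_structure(ms, k=3):
    return StructureModel(pcs=pca_structure(ms, k).pcs,
                          variance_explained=np.empty(0),
                          grm=grm_vanraden(ms))


class TestPca:
    def test_identical_samples_identical_scores(self):
        ms = random_marker_set(0, n=20)
        ms.calls[1] = ms.calls[0]
        st = pca_structure(ms, 3)
        assert np.allclose(st.pcs[0], st.pcs[1])

    def test_variance_explained_conserved_and_sorted(self):
        ms = random_marker_set(1)
        st = pca_structure(ms, 5)
        full = pca_structure(ms, min(ms.n_samples, ms.n_markers) - 2)
        # all-component percentages sum to 100
        X = ms.calls - ms.calls.mean(axis=0)
        s = np.linalg.svd(X, compute_uv=False)
        assert (100 * s**2 / (s**2).sum()).sum() == pytest.approx(100.0)
        assert np.all(np.diff(st.variance_explained) <= 1e-12)

    def test_two_subpopulations_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(2)
        m = 200
        p1, p2 = rng.uniform(0.1, 0.4, m), rng.uniform(0.6, 0.9, m)
        calls = np.vstack([
            rng.binomial(2, p1, size=(40, m)),
            rng.binomial(2, p2, size=(40, m)),
        ]).astype(float)
        ms = make_marker_set(calls, pos=list(range(1000, 1000 + 1000 * m, 1000)))
        st = pca_structure(ms, 2)
        labels = np.repeat([0, 1], 40)
        assert silhouette_score(st.pcs[:, :1], labels) > 0.5

    def test_k_at_rank_errors(self):
        ms = random_marker_set(3, n=5, m=4)
        with pytest.raises(ValueError, match="rank"):
            pca_structure(ms, 10)


class TestGrm:
    def test_duplicated_sample_rows(self):
        ms = random_marker_set(4, n=15)
        ms.calls[1] = ms.calls[0]
        G = grm_vanraden(ms)
        assert np.allclose(G[0], G[1])
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert np.allclose(G, G.T)

    def test_hw_unrelated_mean_diagonal_near_one(self):
        rng = np.random.default_rng(5)
        m = 2000
        p = rng.uniform(0.1, 0.9, m)
        calls = rng.binomial(2, p, size=(200, m)).astype(float)
        ms = make_marker_set(calls, pos=list(range(1000, 1000 + 1000 * m, 1000)))
        G = grm_vanraden(ms)
        se = np.std(np.diag(G)) / np.sqrt(200)
        assert abs(np.diag(G).mean() - 1.0) < 3 * max(se, 0.01)

    def test_hand_example_3x4(self):
        calls = np.array([[0, 1, 2, 1], [2, 1, 0, 0], [1, 2, 1, 1]], dtype=float)
        ms = make_marker_set(calls)
        p = calls.mean(axis=0) / 2
        W = calls - 2 * p
        expect = W @ W.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(grm_vanraden(ms), expect)

    def test_monomorphic_rejected(self):
        calls = np.array([[0, 1], [0, 2], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="monomorphic"):
            grm_vanraden(make_marker_set(calls))


class TestScan:
    def test_identity_grm_no_pcs_equals_simple_regression(self):
        ms = random_marker_set(6, n=50, m=20)
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 50) + 0.5 * ms.calls[:, 3]
        st = StructureModel(pcs=np.empty((50, 0)), variance_explained=np.empty(0),
                            grm=np.eye(50))
        scan = mlm_scan(y, ms, st, n_pcs=0)
        p_ols = np.array([stats.linregress(ms.calls[:, j], y).pvalue for j in range(20)])
        assert np.allclose(scan.pvalues, p_ols, atol=1e-8)

    def test_wald_matches_dense_gls_oracle(self):
        ms = random_marker_set(8, n=50, m=20)
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 50) + 0.4 * ms.calls[:, 5]
        st = full_structure(ms)
        scan = mlm_scan(y, ms, st)
        n = 50
        G = st.grm
        C = np.column_stack([np.ones(n), st.pcs])
        s, U = np.linalg.eigh(G)
        delta = _null_delta(U.T @ y, U.T @ C, np.maximum(s, 0))
        Vi = np.linalg.inv(G + delta * np.eye(n))
        for j in range(20):
            Xj = np.column_stack([C, ms.calls[:, j]])
            A = Xj.T @ Vi @ Xj
            b = np.linalg.solve(A, Xj.T @ Vi @ y)
            r = y - Xj @ b
            s2 = (r @ Vi @ r) / (n - Xj.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(A)[-1, -1])
            t = b[-1] / se
            p = 2 * stats.t.sf(abs(t), n - Xj.shape[1])
            assert p == pytest.approx(scan.pvalues[j], abs=1e-8)
            assert b[-1] == pytest.approx(scan.effects[j], abs=1e-8)

    def test_affine_invariance_of_pvalues(self):
        ms = random_marker_set(10, n=40)
        rng = np.random.default_rng(11)
        y = rng.normal(2, 1, 40)
        st = full_structure(ms)
        p1 = mlm_scan(y, ms, st).pvalues
        p2 = mlm_scan(5.0 * y - 7.0, ms, st).pvalues
        assert np.allclose(p1, p2, atol=1e-8)

    def test_collinear_snp_flagged(self):
        ms = random_marker_set(12, n=30, m=10)
        ms.calls[:, 4] = 1.0  # constant dosage: collinear with intercept
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 30)
        st = StructureModel(pcs=np.empty((30, 0)), variance_explained=np.empty(0),
                            grm=np.eye(30))
        scan = mlm_scan(y, ms, st, n_pcs=0)
        assert "M5" in scan.flagged
        assert scan.pvalues[4] == 1.0 and scan.effects[4] == 0.0

    def test_null_type_one_error_calibration(self):
        rng = np.random.default_rng(14)
        n, m = 300, 400
        rejections, total = 0, 0
        for rep in range(3):
            p = rng.uniform(0.1, 0.9, m)
            calls = rng.binomial(2, p, size=(n, m)).astype(float)
            ms = make_marker_set(calls, pos=list(range(1000, 1000 + 1000 * m, 1000)))
            y = rng.normal(0, 1, n)
            scan = mlm_scan(y, ms, full_structure(ms))
            rejections += int((scan.pvalues < 0.05).sum())
            total += m
        lo, hi = stats.binom.interval(0.95, total, 0.05)
        assert lo <= rejections <= hi


class TestPermutation:
    def test_threshold_bracketed_by_bonferroni_and_alpha(self):
        ms = random_marker_set(15, n=80, m=40)
        rng = np.random.default_rng(16)
        y = rng.normal(0, 1, 80)
        st = full_structure(ms)
        thr = permutation_threshold(y, ms, st, n_perm=60, alpha=0.05, seed=2)
        assert 0.05 / 40 / 5 < thr < 0.05  # loose Bonferroni-side bracket

    def test_duplicated_markers_do_not_halve_threshold(self):
        ms = random_marker_set(17, n=80, m=30)
        dup = make_marker_set(
            np.repeat(ms.calls, 2, axis=1),
            pos=list(range(1000, 1000 + 500 * 60, 500)),
        )
        rng = np.random.default_rng(18)
        y = rng.normal(0, 1, 80)
        t1 = permutation_threshold(y, ms, full_structure(ms), n_perm=80, seed=3)
        t2 = permutation_threshold(y, dup, full_structure(dup), n_perm=80, seed=3)
        # effective test count is unchanged, so thresholds stay comparable
        assert t2 > t1 / 3

    def test_low_n_perm_warns(self):
        ms = random_marker_set(19, n=30, m=10)
        y = np.random.default_rng(20).normal(0, 1, 30)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_threshold(y, ms, full_structure(ms), n_perm=10, seed=4)


class TestSummary:
    def test_empty_when_nothing_significant(self):
        ms = random_marker_set(21, n=40)
        y = np.random.default_rng(22).normal(0, 1, 40)
        scan = mlm_scan(y, ms, full_structure(ms))
        tab = summarize_scan(scan, ms, threshold=1e-12)
        assert tab.empty

    def test_maf_in_range_and_sorted_layout(self):
        ms = random_marker_set(23, n=60)
        rng = np.random.default_rng(24)
        y = rng.normal(0, 1, 60) + 0.8 * ms.calls[:, 2]
        scan = mlm_scan(y, ms, full_structure(ms))
        tab = summarize_scan(scan, ms, threshold=0.5)
        assert ((tab["maf"] > 0) & (tab["maf"] <= 0.5)).all()
        assert tab.equals(tab.sort_values(["trait", "chrom", "pos"]).reset_index(drop=True))
        assert (tab["polymorphism"] == "A > G").all()

    def test_planted_qtl_detected_with_power(self):
        detected = 0
        n_runs = 10
        for s in range(n_runs):
            rng = np.random.default_rng(300 + s)
            n, m = 400, 60
            p = rng.uniform(0.2, 0.8, m)
            calls = rng.binomial(2, p, size=(n, m)).astype(float)
            ms = make_marker_set(calls, pos=list(range(1000, 1000 + 1000 * m, 1000)))
            x = calls[:, 30]
            # effect sized to ~5% of phenotypic variance
            var_x = x.var()
            alpha = np.sqrt(0.05 / var_x / 0.95)
            y = alpha * x + rng.normal(0, 1, n)
            scan = mlm_scan(y, ms, full_structure(ms))
            tab = summarize_scan(scan, ms, threshold=0.05 / m)
            detected += int("M31" in set(tab["snp"]))
        assert detected >= 8
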