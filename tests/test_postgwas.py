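import numpy as np
import pandas as pd
import pytest

from introgmap.gwas import GwasScan
from introgmap.postgwas import (
    allele_origin,
    fit_ld_decay,
    hill_weir_expectation,
    ld_pairwise,
    predict_generation,
    rank_families,
    validate_prediction,
)

from conftest import make_marker_set


def scan_for(ms, effects, significant=None):
    m = ms.n_markers
    eff = np.zeros(m)
    for name, a in effects.items():
        eff[ms.names.index(name)] = a
    p = np.ones(m)
    sig = significant or list(effects)
    for s in sig:
        p[ms.names.index(s)] = 1e-8
    scan = GwasScan(trait="t", snp=ms.names, pvalues=p, effects=eff,
                    maf=np.full(m, 0.2), marker_h2=np.zeros(m),
                    partial_r2=np.zeros(m), threshold=1e-6)
    return scan


class TestLdPairwise:
    def test_duplicated_columns_r2_one_at_distance_zero(self):
        calls = np.random.default_rng(0).binomial(2, 0.5, size=(20, 2)).astype(float)
        calls[:, 1] = calls[:, 0]
        ms = make_marker_set(calls, pos=[1000, 1000])
        out = ld_pairwise(ms, 1)
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        assert out["dist"].iloc[0] == 0.0

    def test_two_marker_hand_fixture(self):
        calls = np.array([[0, 2], [1, 1], [2, 0], [2, 2], [0, 0]], dtype=float)
        ms = make_marker_set(calls, pos=[100, 900])
        out = ld_pairwise(ms, 1)
        expect = np.corrcoef(calls[:, 0], calls[:, 1])[0, 1] ** 2
        assert out["r2"].iloc[0] == pytest.approx(expect)
        assert out["dist"].iloc[0] == 800.0

    def test_independent_markers_mean_r2_near_1_over_n(self):
        rng = np.random.default_rng(1)
        n, m = 50, 60
        calls = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        keep = calls.std(axis=0) > 0
        calls = calls[:, keep]
        ms = make_marker_set(calls, pos=list(range(1000, 1000 + 1000 * calls.shape[1], 1000)))
        out = ld_pairwise(ms, 1)
        se = out["r2"].std() / np.sqrt(len(out) / 10)  # pairs share markers
        assert abs(out["r2"].mean() - 1.0 / n) < 3 * max(se, 0.005)

    def test_swap_invariance_and_subsampling(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.4, size=(30, 10)).astype(float)
        ms = make_marker_set(calls)
        full = ld_pairwise(ms, 1)
        # r2 is symmetric in the pair by construction; check count
        assert len(full) == 45
        sub = ld_pairwise(ms, 1, max_pairs=10, seed=5)
        assert len(sub) == 10

    def test_single_marker_chromosome_empty(self):
        ms = make_marker_set(np.zeros((5, 1)) + np.arange(5)[:, None] % 3)
        assert ld_pairwise(ms, 2).empty


class TestLdDecay:
    def test_monotone_nonincreasing_expectation(self):
        d = np.linspace(0, 1e6, 200)
        e = hill_weir_expectation(d, beta=1e-5, n=100)
        assert np.all(np.diff(e) <= 1e-12)
        assert hill_weir_expectation(0, 1e-5, 100) >= e.max() - 1e-12

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        beta = 2e-5
        errs = []
        for _ in range(20):
            d = rng.uniform(0, 4e5, 400)
            r2 = hill_weir_expectation(d, beta, 150) + rng.normal(0, 0.02, 400)
            fit = fit_ld_decay(pd.DataFrame({"dist": d, "r2": r2}), n=150)
            errs.append(fit.beta)
        assert abs(np.mean(errs) - beta) / beta < 0.10

    def test_flat_data_infinite_half_decay(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 1e5, 100)
        r2 = np.full(100, hill_weir_expectation(0.0, 1.0, 80))
        fit = fit_ld_decay(pd.DataFrame({"dist": d, "r2": r2}), n=80)
        assert np.isinf(fit.half_decay_bp)

    def test_half_decay_consistent_with_curve(self):
        rng = np.random.default_rng(5)
        beta = 5e-5
        d = rng.uniform(0, 3e5, 500)
        r2 = hill_weir_expectation(d, beta, 120) + rng.normal(0, 0.01, 500)
        fit = fit_ld_decay(pd.DataFrame({"dist": d, "r2": r2}), n=120)
        e0 = fit.expectation(0.0)
        assert fit.expectation(fit.half_decay_bp) == pytest.approx(e0 / 2, rel=1e-6)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="10"):
            fit_ld_decay(pd.DataFrame({"dist": [1.0] * 5, "r2": [0.2] * 5}), n=50)


class TestAlleleOrigin:
    def _ms(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, 0.3, size=(40, 4)).astype(float)
        fam = ["FAM01"] * 20 + ["FAM02"] * 20
        return make_marker_set(calls, family=fam)

    def test_forced_origin_cases(self):
        ms = self._ms()
        scan = scan_for(ms, {"M1": 0.5, "M2": 0.5, "M3": -0.4})
        recurrent = np.array([0.0, 2.0, 0.0, 0.0])
        rep = allele_origin(scan, ms, recurrent, snps=["M1", "M2", "M3"])
        t = rep.table.set_index("snp")
        # recurrent ref/ref and alt increases trait -> superior is landrace
        assert t.loc["M1", "superior_origin"] == "landrace"
        # recurrent alt/alt and alt increases trait -> superior is recurrent
        assert t.loc["M2", "superior_origin"] == "recurrent"
        # recurrent ref/ref and ref increases trait -> superior is recurrent
        assert t.loc["M3", "superior_origin"] == "recurrent"

    def test_fixed_family_frequency_zero(self):
        ms = self._ms()
        ms.calls[:20, 0] = 0.0  # FAM01 fixed ref at M1
        scan = scan_for(ms, {"M1": 0.5})
        rep = allele_origin(scan, ms, np.zeros(4), snps=["M1"])
        assert rep.family_freq.loc["FAM01", "M1"] == 0.0

    def test_heterozygous_recurrent_flagged(self):
        ms = self._ms()
        scan = scan_for(ms, {"M1": 0.5})
        rep = allele_origin(scan, ms, np.array([1.0, 0, 0, 0]), snps=["M1"])
        assert rep.table.iloc[0]["superior_origin"] == "undefined"

    def test_repolarization_invariance(self):
        # flipping ref/alt labels (dosage -> 2 - dosage, effect sign flips)
        # leaves origins and superior-allele frequencies unchanged
        ms = self._ms()
        scan = scan_for(ms, {"M1": 0.5})
        rep1 = allele_origin(scan, ms, np.zeros(4), snps=["M1"])
        flipped = make_marker_set(2.0 - ms.calls, family=list(ms.family),
                                  ref="G", alt="A")
        scan2 = scan_for(flipped, {"M1": -0.5})
        rec2 = np.array([2.0, 2.0, 2.0, 2.0])
        rep2 = allele_origin(scan2, flipped, rec2, snps=["M1"])
        assert rep1.table.iloc[0]["superior_origin"] == rep2.table.iloc[0]["superior_origin"]
        pd.testing.assert_series_equal(rep1.family_freq["M1"], rep2.family_freq["M1"])


class TestRankFamilies:
    def _report(self, freq):
        from introgmap.postgwas import OriginReport

        table = pd.DataFrame({
            "snp": list(freq.columns),
            "superior_origin": ["landrace"] * freq.shape[1],
        })
        return OriginReport(table=table, family_freq=freq)

    def test_single_snp_ranking_equals_frequency_order(self):
        freq = pd.DataFrame({"M1": [0.9, 0.1, 0.5]}, index=["A", "B", "C"])
        out = rank_families(self._report(freq))
        assert list(out.index) == ["A", "C", "B"]

    def test_dominant_family_is_first_with_minimum_rank_sum(self):
        freq = pd.DataFrame({"M1": [0.9, 0.1], "M2": [0.8, 0.2], "M3": [0.7, 0.3]},
                            index=["A", "B"])
        out = rank_families(self._report(freq))
        assert out.index[0] == "A" and out.loc["A", "rank_sum"] == 3.0

    def test_matches_brute_force_rank_sums(self):
        rng = np.random.default_rng(7)
        freq = pd.DataFrame(rng.uniform(0, 1, size=(20, 10)),
                            index=[f"F{i:02d}" for i in range(20)],
                            columns=[f"M{j + 1}" for j in range(10)])
        out = rank_families(self._report(freq))
        from scipy.stats import rankdata

        brute = sum(rankdata(-freq[c]) for c in freq.columns)
        assert np.allclose(out.loc[freq.index, "rank_sum"], brute)

    def test_no_qualifying_snps_errors(self):
        freq = pd.DataFrame({"M1": [0.5, 0.5]}, index=["A", "B"])
        rep = self._report(freq)
        rep.table["superior_origin"] = "recurrent"
        with pytest.raises(ValueError, match="landrace_origin"):
            rank_families(rep, mode="landrace_origin")


class TestValidation:
    def test_hand_arithmetic_and_linearity(self):
        calls = np.array([[0.0], [1.0], [2.0]])
        ms2 = make_marker_set(calls)
        yhat = predict_generation(pd.Series({"M1": 0.5}), ms2)
        assert np.allclose(yhat, [0.0, 0.5, 1.0])
        yhat2 = predict_generation(pd.Series({"M1": 1.0}), ms2)
        assert np.allclose(yhat2, 2 * yhat)

    def test_zero_effects_zero_predictions(self, tiny_marker_set):
        eff = pd.Series(0.0, index=["M1", "M3"])
        assert (predict_generation(eff, tiny_marker_set) == 0).all()

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, 0.4, size=(10, 3)).astype(float)
        ms = make_marker_set(calls)
        eff = pd.Series({"M1": 0.3, "M2": -0.2})
        yhat = predict_generation(eff, ms)
        perm = rng.permutation(10)
        ms_p = ms.take_samples(perm)
        yhat_p = predict_generation(eff, ms_p)
        assert np.allclose(yhat_p.to_numpy(), yhat.to_numpy()[perm])

    def test_missing_snp_errors(self, tiny_marker_set):
        with pytest.raises(KeyError, match="M99"):
            predict_generation(pd.Series({"M99": 0.1}), tiny_marker_set)

    def test_perfect_prediction_r_one(self):
        idx = [f"S{i}" for i in range(5)]
        y = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        out = validate_prediction(y, y)
        assert out.r == pytest.approx(1.0)

    def test_null_correlation_near_zero(self):
        rng = np.random.default_rng(9)
        idx = [f"S{i}" for i in range(174)]
        rs = []
        for _ in range(60):
            a = pd.Series(rng.normal(0, 1, 174), index=idx)
            b = pd.Series(rng.normal(0, 1, 174), index=idx)
            rs.append(validate_prediction(a, b).r)
        se = 1 / np.sqrt(174) / np.sqrt(60)
        assert abs(np.mean(rs)) < 3 * se

    def test_zero_variance_flagged(self):
        idx = ["a", "b", "c"]
        with pytest.warns(UserWarning, match="zero variance"):
            out = validate_prediction(pd.Series(1.0, index=idx),
                                      pd.Series([1.0, 2.0, 3.0], index=idx))
        assert np.isnan(out.r)
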