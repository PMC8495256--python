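"""Benchmark routines: worked examples and parameter-recovery studies.

These functions re-run the package's estimators against simulated data
whose ground truth is known, or against closed-form worked examples, and
return the measured quantities.  They back both the test suite and the
reproduction script.  Problem sizes are desk scale: single trials of a
few hundred plots, a few hundred genotypes, and marker panels of a few
hundred SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gwas import (
    StructureModel,
    _gls_snp_tests,
    _null_delta,
    grm_vanraden,
    mlm_scan,
    pca_structure,
    permutation_threshold,
    summarize_scan,
)
from .markers import MarkerSet
from .postgwas import fit_ld_decay, hill_weir_expectation, predict_generation, validate_prediction
from .simulate import BreedingScenario, TrialScenario, select_and_advance, simulate_backcross_genotypes, simulate_trials
from .spatial import SpatialTrialModel, ar1_correlation, fit_spatial_reml
from .stage2 import WeightedJointModel, heritability

__all__ = [
    "heritability_from_printed",
    "simulate_spatial_trial",
    "spatial_grid_oracle_gap",
    "spatial_rho_recovery",
    "stage2_recovery",
    "mlm_type1_rate",
    "permutation_genomewide_rate",
    "gls_oracle_max_abs_diff",
    "closed_loop_validation_r",
    "ld_decay_recovery_error",
    "default_breeding_entry_counts",
]


def heritability_from_printed(sigma_g2, sigma_gs2, cvg, cve, l, r):
    """Heritability from second-stage components with sigma_e2 recovered from CVs.

    The grand mean implied by the genetic coefficient of variation is
    ``100 sqrt(sigma_g2) / CVg``; the residual SD follows from CVe, and the
    genotype-mean heritability formula is applied to the reconstructed
    components.
    """
    mean = 100.0 * np.sqrt(sigma_g2) / cvg
    sigma_e = cve * mean / 100.0
    return heritability(sigma_g2, sigma_gs2, sigma_e**2, l, r)


# ---------------------------------------------------------------------------
# spatial stage 1


def simulate_spatial_trial(n_rows, n_cols, n_geno, rho_row, rho_col,
                           s2_spatial, s2_nugget, seed, mean=5.0, geno_sd=0.7):
    """One rectangular trial with genotypes replicated across the grid."""
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    entries = np.repeat(np.arange(n_geno), -(-n // n_geno))[:n]
    rng.shuffle(entries)
    lr = np.linalg.cholesky(ar1_correlation(n_rows, rho_row))
    lc = np.linalg.cholesky(ar1_correlation(n_cols, rho_col))
    err = np.sqrt(s2_spatial) * (lr @ rng.standard_normal((n_rows, n_cols)) @ lc.T)
    err += np.sqrt(s2_nugget) * rng.standard_normal((n_rows, n_cols))
    gv = rng.normal(0.0, geno_sd, n_geno)
    recs, k = [], 0
    for c in range(n_cols):
        for r in range(n_rows):
            g = entries[k]
            k += 1
            recs.append((r + 1, c + 1, f"G{g:03d}", mean + gv[g] + err[r, c]))
    return pd.DataFrame(recs, columns=["row", "col", "entry", "yield"]), gv


def spatial_grid_oracle_gap(seed, n_grid=21):
    """Fitted restricted log-likelihood minus a brute-force grid maximum.

    A 6x6 trial is fitted by the REML optimizer; the profiled restricted
    likelihood is then evaluated over an ``n_grid``^3 grid on
    (rho_row, rho_col, nugget/spatial ratio).  A correct optimizer gives a
    non-negative gap up to numerical tolerance.
    """
    plots, _ = simulate_spatial_trial(6, 6, 12, 0.5, 0.3, 1.0, 0.5, seed)
    model = SpatialTrialModel().fit(plots)
    rhos = np.linspace(-0.95, 0.95, n_grid)
    lams = np.geomspace(0.01, 100.0, n_grid)
    probe = SpatialTrialModel()
    best = -np.inf
    for rr in rhos:
        for rc in rhos:
            for lam in lams:
                ll = probe.reml_loglik(plots, rr, rc, 1.0, lam)
                if np.isfinite(ll) and ll > best:
                    best = ll
    return model.loglik_ - best


def spatial_rho_recovery(seed, n_rep=50, n_rows=40, n_cols=30,
                         rho_row=0.5, rho_col=0.3):
    """Mean absolute error of the fitted autocorrelations over replicates."""
    rng = np.random.default_rng(seed)
    err_r, err_c = [], []
    for _ in range(n_rep):
        plots, _ = simulate_spatial_trial(n_rows, n_cols, 100, rho_row, rho_col,
                                          1.0, 0.5, int(rng.integers(2**31)))
        fit = fit_spatial_reml(plots)
        err_r.append(abs(fit.rho_row - rho_row))
        err_c.append(abs(fit.rho_col - rho_col))
    return float(np.mean(err_r)), float(np.mean(err_c))


# ---------------------------------------------------------------------------
# stage 2


def simulate_stage2(seed, n_geno=500, n_sites=3, sg2=0.3, sgs2=0.2, se2=1.0):
    """Weighted two-stage input with known components.

    Stage-1 weights (squared-SE surrogates) vary log-uniformly over
    [0.25, 4], reflecting the several-fold spread between unreplicated and
    replicated entries across trials of different error variance.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(sg2), n_geno)
    w = np.exp(rng.uniform(np.log(0.25), np.log(4.0), size=(n_geno, n_sites)))
    gs = rng.normal(0, np.sqrt(sgs2), size=(n_geno, n_sites))
    e = rng.standard_normal((n_geno, n_sites)) * np.sqrt(se2 * w)
    recs = []
    for i in range(n_geno):
        for s in range(n_sites):
            recs.append((f"G{i:03d}", f"S{s}", 1.0 + 0.1 * s + g[i] + gs[i, s] + e[i, s], w[i, s]))
    return pd.DataFrame(recs, columns=["entry", "site", "value", "weight"])


def stage2_recovery(seed, n_rep=30, truth=(0.3, 0.2, 1.0)):
    """Mean REML component estimates over simulation replicates."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rep):
        df = simulate_stage2(int(rng.integers(2**31)),
                             sg2=truth[0], sgs2=truth[1], se2=truth[2])
        m = WeightedJointModel().fit(df)
        out.append((m.sigma_g2_, m.sigma_gs2_, m.sigma_e2_))
    return tuple(np.mean(out, axis=0))


# ---------------------------------------------------------------------------
# GWAS


def _null_panel(rng, n, m):
    p = rng.uniform(0.1, 0.9, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(float)
    mono = calls.std(axis=0) == 0
    calls[0, mono] = np.abs(calls[0, mono] - 1)
    mp = pd.DataFrame({"name": [f"M{j + 1}" for j in range(m)], "chrom": 1,
                       "pos": np.arange(1, m + 1) * 1000, "ref": "A", "alt": "G"})
    return MarkerSet([f"S{i}" for i in range(n)], ["F"] * n, ["BC1S1"] * n, calls, mp)


def mlm_type1_rate(seed, n=300, m=400, n_scans=3, alpha=0.05):
    """Per-marker empirical type-I error of the MLM scan on null phenotypes."""
    rng = np.random.default_rng(seed)
    rej, total = 0, 0
    for _ in range(n_scans):
        ms = _null_panel(rng, n, m)
        y = rng.normal(0, 1, n)
        st = StructureModel(pcs=pca_structure(ms, 3).pcs,
                            variance_explained=np.empty(0), grm=grm_vanraden(ms))
        scan = mlm_scan(y, ms, st)
        rej += int((scan.pvalues < alpha).sum())
        total += m
    return rej / total, total


def permutation_genomewide_rate(seed, n_rep=200, n=100, m=200, n_perm=100, alpha=0.05):
    """Genome-wide type-I error at the permutation threshold on null data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        ms = _null_panel(rng, n, m)
        y = rng.normal(0, 1, n)
        st = StructureModel(pcs=pca_structure(ms, 3).pcs,
                            variance_explained=np.empty(0), grm=grm_vanraden(ms))
        thr = permutation_threshold(y, ms, st, n_perm=n_perm, alpha=alpha,
                                    seed=int(rng.integers(2**31)))
        scan = mlm_scan(y, ms, st)
        hits += int(scan.pvalues.min() < thr)
    return hits / n_rep, n_rep


def gls_oracle_max_abs_diff(seed, n=50, m=20):
    """Max |p - p_bruteforce| between the scan and explicit dense GLS."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    ms = _null_panel(rng, n, m)
    y = rng.normal(0, 1, n) + 0.4 * ms.calls[:, m // 2]
    st = StructureModel(pcs=pca_structure(ms, 3).pcs,
                        variance_explained=np.empty(0), grm=grm_vanraden(ms))
    scan = mlm_scan(y, ms, st)
    C = np.column_stack([np.ones(n), st.pcs])
    s, U = np.linalg.eigh(st.grm)
    delta = _null_delta(U.T @ y, U.T @ C, np.maximum(s, 0))
    Vi = np.linalg.inv(st.grm + delta * np.eye(n))
    worst = 0.0
    for j in range(m):
        Xj = np.column_stack([C, ms.calls[:, j]])
        A = Xj.T @ Vi @ Xj
        b = np.linalg.solve(A, Xj.T @ Vi @ y)
        r = y - Xj @ b
        s2 = (r @ Vi @ r) / (n - Xj.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(A)[-1, -1])
        p = 2 * sps.t.sf(abs(b[-1] / se), n - Xj.shape[1])
        worst = max(worst, abs(p - scan.pvalues[j]))
    return worst


# ---------------------------------------------------------------------------
# closed loop and LD


def closed_loop_validation_r(seed):
    """Correlation of next-generation predictions with planted genetic values.

    BC1S1 lines are simulated with a handful of additive QTL; the
    phenotype is exactly the planted-QTL genetic value.  Significant SNPs
    and effects from the BC1S1 scan predict BC1S2 genetic values, which
    are compared with the BC1S2 truth.
    """
    sc = BreedingScenario(n_families=10, lines_per_family=40, n_chromosomes=5,
                          markers_per_chromosome=20, seed=seed,
                          qtl=[(10, 0.8, "both"), (45, -0.6, "both"), (78, 0.7, "both")])
    ms, _ = simulate_backcross_genotypes(sc)
    q_idx = [q[0] for q in sc.qtl]
    q_eff = np.array([q[1] for q in sc.qtl])
    y1 = ms.calls[:, q_idx] @ q_eff
    st = StructureModel(pcs=pca_structure(ms, 3).pcs,
                        variance_explained=np.empty(0), grm=grm_vanraden(ms))
    scan = mlm_scan(y1, ms, st, trait="closed-loop")
    thr = permutation_threshold(y1, ms, st, n_perm=100, seed=seed + 1)
    scan.threshold = thr
    sig = scan.significant
    if not sig:  # fall back to the strongest associations
        sig = [scan.snp[j] for j in np.argsort(scan.pvalues)[:3]]
    effects = pd.Series({s: scan.effects[scan.snp.index(s)] for s in sig})
    ms2 = select_and_advance(ms, ms.samples[:64], seed=seed + 2)
    yhat2 = predict_generation(effects, ms2)
    y2 = pd.Series(ms2.calls[:, q_idx] @ q_eff, index=ms2.samples)
    return validate_prediction(yhat2, y2, trait="closed-loop").r


def ld_decay_recovery_error(seed, beta=2e-5, n=150, n_rep=20):
    """Relative error of the mean fitted decay parameter over replicates."""
    rng = np.random.default_rng(seed)
    betas = []
    for _ in range(n_rep):
        d = rng.uniform(0, 4e5, 400)
        r2 = hill_weir_expectation(d, beta, n) + rng.normal(0, 0.02, 400)
        fit = fit_ld_decay(pd.DataFrame({"dist": d, "r2": r2}), n=n)
        betas.append(fit.beta)
    return abs(float(np.mean(betas)) - beta) / beta


# ---------------------------------------------------------------------------
# generator design fidelity


def default_breeding_entry_counts(seed):
    """(distinct test genotypes, BC1S2 line count) under the default scheme.

    Runs the default breeding scenario (20 families x 74 BC1F1 lines), the
    default sparse trial allocation, and the default selection/advance
    step (64 fertile selected lines).
    """
    sc = BreedingScenario(markers_per_chromosome=2, seed=seed)
    ms, _ = simulate_backcross_genotypes(sc)
    plots, _ = simulate_trials(ms, TrialScenario(seed=seed + 1), sc)
    n_test = int(plots.loc[~plots["is_check"], "entry"].nunique())
    bc1s2 = select_and_advance(ms, ms.samples[:64], seed=seed + 2)
    return n_test, bc1s2.n_samples
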