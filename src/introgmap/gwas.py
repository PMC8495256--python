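"""Population structure, VanRaden GRM, and single-marker mixed-model GWAS.

The association model for each SNP is

    g = X beta + Z u + e,   u ~ N(0, sigma2_u * G),  e ~ N(0, sigma2_e * I)

where ``X`` holds the intercept, the first k genomic principal components
(k = 3 by default) and one SNP at a time, and ``G`` is VanRaden's genomic
relationship matrix ``W W' / (2 sum p_k (1 - p_k))`` from 2p-centred
dosages.  The variance ratio ``delta = sigma2_e / sigma2_u`` is estimated
once by REML under the no-SNP null and held fixed across markers
(population parameters previously determined); each SNP is then tested by
a GLS Wald/t test after rotating the data by the eigendecomposition of
``G + delta I``.  A per-SNP REML option exists behind the
``per_snp_reml`` flag.

The genome-wide significance threshold is the empirical alpha-quantile of
minimum scan p-values across seeded phenotype permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .markers import MarkerSet

__all__ = [
    "StructureModel",
    "GwasScan",
    "MixedLMAssociation",
    "pca_structure",
    "grm_vanraden",
    "mlm_scan",
    "permutation_threshold",
    "summarize_scan",
]


@dataclass
class StructureModel:
    """Genomic PCs and relationship matrix for population-structure control."""

    pcs: np.ndarray  # samples x k scores
    variance_explained: np.ndarray  # % per retained PC, non-increasing
    grm: np.ndarray | None = None


@dataclass
class GwasScan:
    """Per-SNP association results for one trait."""

    trait: str
    snp: list
    pvalues: np.ndarray
    effects: np.ndarray
    maf: np.ndarray
    marker_h2: np.ndarray
    partial_r2: np.ndarray
    threshold: float | None = None
    n_pcs: int = 0
    flagged: list = field(default_factory=list)  # SNPs collinear with covariates

    @property
    def significant(self):
        if self.threshold is None:
            return []
        return [s for s, p in zip(self.snp, self.pvalues) if p < self.threshold]


def _dosage(ms_or_array) -> np.ndarray:
    x = ms_or_array.calls if isinstance(ms_or_array, MarkerSet) else np.asarray(ms_or_array, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("genotypes contain missing calls; impute first")
    return x


def pca_structure(ms, k: int = 3) -> StructureModel:
    """Principal components of the 2p-centred dosage matrix (no scaling)."""
    X = _dosage(ms)
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    r = np.linalg.matrix_rank(W)
    if k >= r:
        raise ValueError(f"k={k} must be below the centred-genotype rank {r}")
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    var = s**2
    expl = 100.0 * var / var.sum()
    return StructureModel(pcs=U[:, :k] * s[:k], variance_explained=expl[:k])


def grm_vanraden(ms) -> np.ndarray:
    """VanRaden GRM: W W' / (2 sum p_k (1-p_k)), W = calls - 2p."""
    X = _dosage(ms)
    p = X.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    if np.any(het <= 0):
        raise ValueError("monomorphic markers present; run QC filtering first")
    W = X - 2.0 * p
    return (W @ W.T) / (2.0 * het.sum())


# ---------------------------------------------------------------------------
# MLM scan


def _null_delta(yr, Xr, s):
    """REML estimate of delta = sigma2_e/sigma2_u on rotated data.

    ``yr, Xr`` are the phenotype and covariates rotated by the
    eigenvectors of G; ``s`` the eigenvalues.  Returns delta.
    """
    n, p = Xr.shape

    def nll(logd):
        d = np.exp(logd)
        w = 1.0 / (s + d)
        XtWX = Xr.T @ (w[:, None] * Xr)
        sign, ld_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, Xr.T @ (w * yr))
        quad = float(yr @ (w * yr)) - float((Xr.T @ (w * yr)) @ beta)
        if quad <= 0:
            return np.inf
        s2 = quad / (n - p)
        return 0.5 * ((n - p) * np.log(s2) + float(np.sum(np.log(s + d))) + ld_x)

    grid = np.linspace(-8, 8, 17)
    vals = [nll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


def _gls_snp_tests(yr, Cr, Xr, s, delta):
    """Per-SNP GLS t-tests with the variance ratio fixed.

    Operates on rotated data: whitening by ``1/sqrt(s + delta)`` turns the
    mixed model into OLS, and partialling the covariates out of phenotype
    and SNPs (Frisch-Waugh) gives every SNP's slope, t statistic and
    two-sided p in one vectorized pass.  Returns
    ``(pvals, effects, tstats, flagged indices)``.
    """
    n, p = Cr.shape
    sw = 1.0 / np.sqrt(s + delta)
    Ct = sw[:, None] * Cr
    yt = sw * yr
    Xt = sw[:, None] * Xr
    Q, _ = np.linalg.qr(Ct)
    ry = yt - Q @ (Q.T @ yt)
    RX = Xt - Q @ (Q.T @ Xt)
    sxx = np.einsum("ij,ij->j", RX, RX)
    tol = 1e-10 * np.maximum(np.einsum("ij,ij->j", Xt, Xt), 1.0)
    ok = sxx > tol
    df = n - p - 1
    beta = np.zeros(Xr.shape[1])
    tstat = np.zeros(Xr.shape[1])
    pvals = np.ones(Xr.shape[1])
    sxy = RX.T @ ry
    beta[ok] = sxy[ok] / sxx[ok]
    syy = float(ry @ ry)
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = np.where(ok & (se > 0), beta / se, 0.0)
    tstat[ok] = t[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    flagged = list(np.where(~ok)[0])
    return pvals, beta, tstat, flagged


class MixedLMAssociation(BaseEstimator):
    """Single-marker mixed-linear-model association scan.

    Parameters
    ----------
    n_pcs : int
        Number of genomic principal components included as fixed
        covariates (0 disables structure correction).
    per_snp_reml : bool
        Re-estimate the variance ratio for every SNP instead of reusing
        the null estimate (slower; off by default).

    Fitted attributes: ``pvalues_``, ``effects_``, ``maf_``,
    ``marker_h2_``, ``partial_r2_``, ``delta_``, ``flagged_``.
    """

    def __init__(self, n_pcs: int = 3, per_snp_reml: bool = False):
        self.n_pcs = n_pcs
        self.per_snp_reml = per_snp_reml

    def fit(self, ms, y, structure: StructureModel | None = None):
        X = _dosage(ms)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        if y.shape != (n,):
            raise ValueError("phenotype not aligned with samples")
        if structure is None:
            structure = StructureModel(
                pcs=pca_structure(ms, self.n_pcs).pcs if self.n_pcs else np.empty((n, 0)),
                variance_explained=np.empty(0),
                grm=grm_vanraden(ms),
            )
        G = structure.grm if structure.grm is not None else grm_vanraden(ms)
        pcs = structure.pcs[:, : self.n_pcs] if self.n_pcs else np.empty((n, 0))

        s, U = np.linalg.eigh(G)
        s = np.maximum(s, 0.0)
        C = np.column_stack([np.ones(n), pcs])
        yr = U.T @ y
        Cr = U.T @ C
        Xr = U.T @ X

        delta = _null_delta(yr, Cr, s)
        self.delta_ = delta

        if self.per_snp_reml:
            pvals = np.ones(m)
            effects = np.zeros(m)
            tstat = np.zeros(m)
            flagged = []
            df = n - C.shape[1] - 1
            for j in range(m):
                dj = _null_delta(yr, np.column_stack([Cr, Xr[:, j]]), s)
                pj, ej, tj, fj = _gls_snp_tests(yr, Cr, Xr[:, j : j + 1], s, dj)
                pvals[j], effects[j], tstat[j] = pj[0], ej[0], tj[0]
                if fj:
                    flagged.append(j)
        else:
            pvals, effects, tstat, flagged = _gls_snp_tests(yr, Cr, Xr, s, delta)
            df = n - C.shape[1] - 1

        p_alt = X.mean(axis=0) / 2.0
        maf = np.minimum(p_alt, 1.0 - p_alt)
        var_y = float(np.var(y))
        marker_h2 = 2.0 * p_alt * (1 - p_alt) * effects**2 / var_y if var_y > 0 else np.zeros(m)
        partial_r2 = tstat**2 / (tstat**2 + df)
        if flagged:
            partial_r2[flagged] = 0.0

        self.pvalues_ = np.clip(pvals, np.finfo(float).tiny, 1.0)
        self.effects_ = effects
        self.maf_ = maf
        self.marker_h2_ = marker_h2
        self.partial_r2_ = partial_r2
        self.flagged_ = flagged
        self.structure_ = structure
        return self


def mlm_scan(y, ms, structure: StructureModel | None = None, n_pcs: int = 3,
             trait: str = "trait", per_snp_reml: bool = False) -> GwasScan:
    """Run the MLM scan and return a :class:`GwasScan`."""
    model = MixedLMAssociation(n_pcs=n_pcs, per_snp_reml=per_snp_reml).fit(ms, y, structure)
    names = ms.names if isinstance(ms, MarkerSet) else [f"M{j + 1}" for j in range(model.pvalues_.size)]
    return GwasScan(
        trait=trait,
        snp=names,
        pvalues=model.pvalues_,
        effects=model.effects_,
        maf=model.maf_,
        marker_h2=model.marker_h2_,
        partial_r2=model.partial_r2_,
        n_pcs=n_pcs,
        flagged=[names[j] for j in model.flagged_],
    )


def permutation_threshold(y, ms, structure: StructureModel | None = None,
                          n_perm: int = 100, alpha: float = 0.05,
                          seed: int | None = None, n_pcs: int = 3) -> float:
    """Genome-wide p-value threshold from phenotype permutations.

    The phenotype is permuted against samples ``n_perm`` times, the scan
    rerun, and the minimum p recorded; the threshold is the empirical
    alpha-quantile (lower order statistic) of the minimum p-values.
    """
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives an unstable threshold quantile")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    X = _dosage(ms)
    n = len(y)
    if structure is None:
        structure = StructureModel(
            pcs=pca_structure(ms, n_pcs).pcs if n_pcs else np.empty((n, 0)),
            variance_explained=np.empty(0),
            grm=grm_vanraden(ms),
        )
    G = structure.grm if structure.grm is not None else grm_vanraden(ms)
    pcs = structure.pcs[:, :n_pcs] if n_pcs else np.empty((n, 0))
    s, U = np.linalg.eigh(G)
    s = np.maximum(s, 0.0)
    Cr = U.T @ np.column_stack([np.ones(n), pcs])
    Xr = U.T @ X
    mins = np.empty(n_perm)
    for i in range(n_perm):
        yr = U.T @ rng.permutation(y)
        delta = _null_delta(yr, Cr, s)
        pvals, _, _, _ = _gls_snp_tests(yr, Cr, Xr, s, delta)
        mins[i] = pvals.min()
    return float(np.quantile(mins, alpha, method="lower"))


def summarize_scan(scan: GwasScan, ms: MarkerSet, threshold: float) -> pd.DataFrame:
    """Significant-SNP table: position, polymorphism, MAF, effect, h2, r2."""
    rows = []
    pos = ms.map.set_index("name")
    for i, name in enumerate(scan.snp):
        if scan.pvalues[i] >= threshold:
            continue
        r = pos.loc[name]
        rows.append({
            "trait": scan.trait,
            "snp": name,
            "chrom": r["chrom"],
            "pos": int(r["pos"]),
            "polymorphism": f"{r['ref']} > {r['alt']}",
            "maf": float(scan.maf[i]),
            "effect": float(scan.effects[i]),
            "marker_h2": float(scan.marker_h2[i]),
            "partial_r2": float(scan.partial_r2[i]),
            "p": float(scan.pvalues[i]),
        })
    df = pd.DataFrame(rows, columns=["trait", "snp", "chrom", "pos", "polymorphism",
                                     "maf", "effect", "marker_h2", "partial_r2", "p"])
    return df.sort_values(["trait", "chrom", "pos"]).reset_index(drop=True)
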