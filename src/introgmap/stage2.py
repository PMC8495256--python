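"""Drought-tolerance index and second-stage weighted joint mixed model.

The Harmonic Mean of Relative Performance (HMRP) for genotype *i* at site
*j* combines the stage-1 adjusted means under well-watered (WW) and
drought (DR) irrigation:

    HMRP_ij = 2 / [ (GYww_ij / ybar_ww_j)^-1 + (GYdr_ij / ybar_dr_j)^-1 ]

Values sit around 1; higher means more drought tolerant.  The index (or
the per-treatment grain-yield BLUEs) then enters the joint model

    y = X beta + Z g + W i + e

with site fixed, genotype and genotype-by-site random, and per-record
residual variance proportional to the stage-1 weight
(``Var(e_ij) = w_ij * sigma2_e``; the weight of an HMRP record is the
mean of the squared WW and DR standard errors).  Because neither random
term links records of different genotypes, the phenotypic covariance is
block-diagonal by genotype and REML reduces to small per-genotype solves.

Broad-sense heritability on a genotype-mean basis is

    h2 = sigma2_g / (sigma2_g + sigma2_gs / l + sigma2_e / (l r))

with *l* sites and *r* replicates; the replicate count is always an
explicit argument (the WW trials are unreplicated, the DR trials have
two replicates).  Accuracy is reported as
``100 * sqrt(1 - mean(PEV) / sigma2_g)`` from the BLUP prediction-error
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "HmrpTable",
    "JointFit",
    "WeightedJointModel",
    "compute_hmrp",
    "fit_joint_reml",
    "heritability",
    "accuracy_and_cv",
    "lrt_test",
]


@dataclass
class JointFit:
    """Stage-2 REML solution for one trait."""

    trait: str
    blups: pd.Series
    site_effects: pd.Series
    sigma_g2: float
    sigma_gs2: float
    sigma_e2: float
    loglik: float
    wald_site: dict
    lrt_genotype: dict
    lrt_gxs: dict
    h2: float | None = None
    accuracy: float | None = None
    cvg: float | None = None
    cve: float | None = None
    n_sites: int = 0
    reps: int | None = None


class HmrpTable(pd.DataFrame):
    """Per genotype x site HMRP values with components and stage-2 weights."""

    @property
    def _constructor(self):
        return HmrpTable


def compute_hmrp(blues: pd.DataFrame, check_entries=()) -> HmrpTable:
    """HMRP per genotype x site from a stage-1 BLUE table.

    ``blues`` needs columns ``entry, site, treatment, blue, se`` with
    treatment in {"WW", "DR"}.  Site means are taken over test entries
    (rows whose entry is not in ``check_entries``).  Genotypes missing one
    treatment at a site, or with a non-positive relative performance, are
    excluded at that site with a warning.
    """
    df = pd.DataFrame(blues)
    need = {"entry", "site", "treatment", "blue", "se"}
    if not need <= set(df.columns):
        raise ValueError(f"BLUE table lacks columns {sorted(need - set(df.columns))}")
    check_entries = set(map(str, check_entries))
    rows = []
    skipped = 0
    for site, sub in df.groupby("site"):
        ww = sub[sub["treatment"] == "WW"].set_index(sub[sub["treatment"] == "WW"]["entry"].astype(str))
        dr = sub[sub["treatment"] == "DR"].set_index(sub[sub["treatment"] == "DR"]["entry"].astype(str))
        test_ww = ww[~ww.index.isin(check_entries)]
        test_dr = dr[~dr.index.isin(check_entries)]
        if test_ww.empty or test_dr.empty:
            continue
        mu_ww = float(test_ww["blue"].mean())
        mu_dr = float(test_dr["blue"].mean())
        for e in test_ww.index:
            if e not in test_dr.index:
                skipped += 1
                continue
            b_ww = float(test_ww.loc[e, "blue"])
            b_dr = float(test_dr.loc[e, "blue"])
            rw, rd = b_ww / mu_ww, b_dr / mu_dr
            if rw <= 0 or rd <= 0:
                skipped += 1
                continue
            weight = 0.5 * (float(test_ww.loc[e, "se"]) ** 2 + float(test_dr.loc[e, "se"]) ** 2)
            rows.append((e, site, 2.0 / (1.0 / rw + 1.0 / rd), b_ww, b_dr, mu_ww, mu_dr, weight))
    if skipped:
        warnings.warn(f"{skipped} genotype x site records excluded from HMRP "
                      "(missing treatment or non-positive relative performance)")
    return HmrpTable(
        rows,
        columns=["entry", "site", "hmrp", "blue_ww", "blue_dr", "site_mean_ww", "site_mean_dr", "weight"],
    )


# ---------------------------------------------------------------------------
# weighted joint REML


class WeightedJointModel(BaseEstimator):
    """REML fit of the weighted two-stage joint mixed model.

    Parameters
    ----------
    include_genotype, include_interaction : bool
        Drop a random term to obtain the reduced models used by the
        likelihood-ratio tests.
    value_col, weight_col, genotype_col, site_col : str
        Column names in the input table.

    Fitted attributes: ``sigma_g2_``, ``sigma_gs2_``, ``sigma_e2_``,
    ``blups_``, ``site_effects_``, ``pev_``, ``loglik_``, ``wald_site_``.
    """

    def __init__(self, include_genotype=True, include_interaction=True,
                 value_col="value", weight_col="weight",
                 genotype_col="entry", site_col="site"):
        self.include_genotype = include_genotype
        self.include_interaction = include_interaction
        self.value_col = value_col
        self.weight_col = weight_col
        self.genotype_col = genotype_col
        self.site_col = site_col

    # -- internals ---------------------------------------------------------

    def _blocks(self, df):
        """Per-genotype record blocks: (weights, site indices, y)."""
        sites = sorted(df[self.site_col].astype(str).unique())
        s_index = {s: i for i, s in enumerate(sites)}
        blocks = {}
        for g, sub in df.groupby(df[self.genotype_col].astype(str), sort=True):
            blocks[g] = (
                sub[self.weight_col].astype(float).to_numpy() if self.weight_col in sub else np.ones(len(sub)),
                sub[self.site_col].astype(str).map(s_index).to_numpy(),
                sub[self.value_col].astype(float).to_numpy(),
            )
        return sites, blocks

    @staticmethod
    def _group_by_shape(blocks):
        """Group genotypes whose blocks share a record count, for batching."""
        groups = {}
        for g, (w, s, y) in blocks.items():
            groups.setdefault(len(y), []).append(g)
        return groups

    def _nll(self, theta_g, theta_gs, sites, blocks, groups, return_aux=False):
        l = len(sites)
        n = sum(len(b[2]) for b in blocks.values())
        p = l
        XtCX = np.zeros((p, p))
        XtCy = np.zeros(p)
        yCy = 0.0
        logdetC = 0.0
        per_geno = {}
        for k, genos in groups.items():
            W = np.array([blocks[g][0] for g in genos])          # (G, k)
            S = np.array([blocks[g][1] for g in genos])          # (G, k) site idx
            Y = np.array([blocks[g][2] for g in genos])          # (G, k)
            G = len(genos)
            same_site = (S[:, :, None] == S[:, None, :]).astype(float)
            C = theta_g + theta_gs * same_site + np.einsum("gk,kl->gkl", W, np.eye(k))
            Ci = np.linalg.inv(C)
            sign, ld = np.linalg.slogdet(C)
            if np.any(sign <= 0):
                return (np.inf, None) if return_aux else np.inf
            logdetC += float(ld.sum())
            X = np.zeros((G, k, p))
            gi = np.repeat(np.arange(G), k)
            X[gi, np.tile(np.arange(k), G), S.ravel()] = 1.0
            CiX = np.einsum("gkl,glp->gkp", Ci, X)
            CiY = np.einsum("gkl,gl->gk", Ci, Y)
            XtCX += np.einsum("gkp,gkq->pq", X, CiX)
            XtCy += np.einsum("gkp,gk->p", X, CiY)
            yCy += float(np.einsum("gk,gk->", Y, CiY))
            if return_aux:
                ones = np.ones(k)
                u = np.einsum("gkl,l->gk", Ci, ones)             # C^-1 1 per geno
                for i, g in enumerate(genos):
                    per_geno[g] = (Ci[i], Y[i], X[i], u[i])
        sign, logdetXtCX = np.linalg.slogdet(XtCX)
        if sign <= 0:
            return (np.inf, None) if return_aux else np.inf
        beta = np.linalg.solve(XtCX, XtCy)
        quad = yCy - float(XtCy @ beta)
        if quad <= 0:
            return (np.inf, None) if return_aux else np.inf
        s2e = quad / (n - p)
        nll = 0.5 * ((n - p) * np.log(s2e) + logdetC + logdetXtCX + (n - p))
        if return_aux:
            return nll, (beta, s2e, XtCX, per_geno)
        return nll

    # -- API ---------------------------------------------------------------

    def fit(self, df: pd.DataFrame, y=None):
        df = pd.DataFrame(df)
        sites, blocks = self._blocks(df)
        if len(sites) < 2:
            raise ValueError("joint analysis needs records from at least 2 sites")
        if self.weight_col in df and (df[self.weight_col].astype(float) <= 0).any():
            raise ValueError("weights must be positive")
        groups = self._group_by_shape(blocks)

        free_g = self.include_genotype
        free_gs = self.include_interaction
        lo, hi = -14.0, 8.0

        def unpack(x):
            i = 0
            tg = np.exp(x[i]) if free_g else 0.0
            i += free_g
            tgs = np.exp(x[i]) if free_gs else 0.0
            return tg, tgs

        def obj(x):
            v = self._nll(*unpack(x), sites, blocks, groups)
            return v if np.isfinite(v) else 1e10

        n_free = int(free_g) + int(free_gs)
        if n_free == 0:
            x_best = np.array([])
        else:
            grid_vals = [np.log(0.02), np.log(0.3), np.log(2.0)]
            import itertools

            starts = sorted(
                ((obj(np.array(x0)), x0) for x0 in itertools.product(grid_vals, repeat=n_free)),
                key=lambda t: t[0],
            )
            best = None
            for _, x0 in starts[:2]:
                res = optimize.minimize(obj, x0=np.array(x0), method="L-BFGS-B",
                                        bounds=[(lo, hi)] * n_free)
                if best is None or res.fun < best.fun:
                    best = res
            x_best = best.x
        theta_g, theta_gs = unpack(x_best)
        nll, aux = self._nll(theta_g, theta_gs, sites, blocks, groups, return_aux=True)
        if aux is None:
            raise RuntimeError("joint REML failed to converge")
        beta, s2e, XtCX, per_geno = aux

        cov_beta = s2e * np.linalg.inv(XtCX)
        # Wald for site: all site means equal (l-1 contrasts)
        L = np.diff(np.eye(len(sites)), axis=0)
        lb = L @ beta
        wstat = float(lb @ np.linalg.solve(L @ cov_beta @ L.T, lb))
        wald_site = {"stat": wstat, "df": len(sites) - 1,
                     "p": float(stats.chi2.sf(wstat, len(sites) - 1))}

        XtCX_inv = np.linalg.inv(XtCX)
        blups, pev = {}, {}
        for g, (Ci, yg, Xg, u) in per_geno.items():
            r = yg - Xg @ beta
            blups[g] = theta_g * float(u @ r)
            ut1 = float(u.sum())            # 1' C^-1 1
            b = Xg.T @ u
            corr = ut1 - float(b @ XtCX_inv @ b)
            pev[g] = max(theta_g * s2e * (1.0 - theta_g * corr), 0.0)

        self.sites_ = sites
        self.sigma_g2_ = float(theta_g * s2e)
        self.sigma_gs2_ = float(theta_gs * s2e)
        self.sigma_e2_ = float(s2e)
        self.blups_ = pd.Series(blups).sort_index()
        self.pev_ = pd.Series(pev).sort_index()
        self.site_effects_ = pd.Series(beta, index=sites)
        self.loglik_ = float(-nll)
        self.wald_site_ = wald_site
        return self


def heritability(sigma_g2: float, sigma_gs2: float, sigma_e2: float, l: int, r: int) -> float:
    """Broad-sense heritability on a genotype-mean basis over l sites, r reps."""
    if l < 1 or r < 1:
        raise ValueError("l and r must be >= 1")
    denom = sigma_g2 + sigma_gs2 / l + sigma_e2 / (l * r)
    return sigma_g2 / denom if denom > 0 else 0.0


def accuracy_and_cv(fit, grand_mean: float):
    """(accuracy %, CVg %, CVe %) for a fitted :class:`WeightedJointModel`.

    Accuracy is ``100 * sqrt(1 - mean(PEV) / sigma2_g)``, 0 when the
    genotypic variance is 0.
    """
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive for CV computation")
    sg2, se2 = fit.sigma_g2_, fit.sigma_e2_
    if sg2 <= 0:
        acc = 0.0
    else:
        acc = 100.0 * float(np.sqrt(max(0.0, 1.0 - fit.pev_.mean() / sg2)))
    cvg = 100.0 * float(np.sqrt(max(sg2, 0.0))) / grand_mean
    cve = 100.0 * float(np.sqrt(max(se2, 0.0))) / grand_mean
    return acc, cvg, cve


def lrt_test(ll_full: float, ll_reduced: float) -> dict:
    """LRT of one variance component against the 50:50 chi2_0/chi2_1 boundary null."""
    if np.ndim(ll_full) or np.ndim(ll_reduced):
        raise TypeError("pass restricted log-likelihood values")
    stat = 2.0 * (ll_full - ll_reduced)
    if stat < -1e-6:
        warnings.warn("reduced model has higher restricted likelihood; consider refitting")
    if stat <= 0:
        p = 1.0
    else:
        p = 0.5 * float(stats.chi2.sf(stat, 1))
    return {"stat": float(stat), "p": p}


def fit_joint_reml(values: pd.DataFrame, trait: str = "HMRP", reps: int | None = None,
                   value_col="value", weight_col="weight",
                   genotype_col="entry", site_col="site") -> JointFit:
    """Fit the full stage-2 model plus the two reduced models for LRTs.

    ``reps`` is the per-trial replicate count used by the heritability
    formula (2 for the RCBD drought trials, 1 for the unreplicated WW
    trials); when None, heritability is not computed.
    """
    kw = dict(value_col=value_col, weight_col=weight_col,
              genotype_col=genotype_col, site_col=site_col)
    full = WeightedJointModel(**kw).fit(values)
    red_g = WeightedJointModel(include_genotype=False, **kw).fit(values)
    red_i = WeightedJointModel(include_interaction=False, **kw).fit(values)
    lrt_g = lrt_test(full.loglik_, red_g.loglik_)
    lrt_i = lrt_test(full.loglik_, red_i.loglik_)
    l = len(full.sites_)
    h2 = heritability(full.sigma_g2_, full.sigma_gs2_, full.sigma_e2_, l, reps) if reps else None
    grand_mean = float(pd.DataFrame(values)[value_col].mean())
    acc = cvg = cve = None
    if grand_mean > 0:
        acc, cvg, cve = accuracy_and_cv(full, grand_mean)
    return JointFit(
        trait=trait,
        blups=full.blups_,
        site_effects=full.site_effects_,
        sigma_g2=full.sigma_g2_,
        sigma_gs2=full.sigma_gs2_,
        sigma_e2=full.sigma_e2_,
        loglik=full.loglik_,
        wald_site=full.wald_site_,
        lrt_genotype=lrt_g,
        lrt_gxs=lrt_i,
        h2=h2,
        accuracy=acc,
        cvg=cvg,
        cve=cve,
        n_sites=l,
        reps=reps,
    )
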