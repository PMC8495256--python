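"""LD decay, allele-origin tracing, family rankings and cross-generation validation.

Linkage disequilibrium between marker pairs is summarized by r^2 (squared
Pearson correlation of dosage columns) against physical distance, and the
decay curve fitted with the Hill-Weir drift expectation

    E[r^2] = (10 + C) / ((2 + C)(11 + C))
             * [1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))]

with C = beta * distance and n the sample size.

For each significant SNP the landrace-origin allele is the allele absent
from the homozygous recurrent parent, and the superior allele the one
whose extra copy increases the trait (sign of the substitution effect
under alt-dosage coding).  Families are ranked by rank-sums of their
superior-allele frequencies; cross-generation validation predicts
next-generation genetic values as ``yhat2 = X alpha1`` (significant-SNP
dosages times first-generation effects) and reports the Pearson
correlation with observed BLUPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .markers import MarkerSet

__all__ = [
    "LdDecayFit",
    "OriginReport",
    "ValidationResult",
    "LdDecayCurve",
    "ld_pairwise",
    "fit_ld_decay",
    "hill_weir_expectation",
    "allele_origin",
    "rank_families",
    "predict_generation",
    "validate_prediction",
]


@dataclass
class LdDecayFit:
    """Fitted LD-decay curve for one chromosome (or pooled pairs)."""

    beta: float
    n: int
    pairs: pd.DataFrame
    half_decay_bp: float  # distance at which E[r^2] halves from its intercept

    def expectation(self, distance_bp):
        return hill_weir_expectation(np.asarray(distance_bp, dtype=float), self.beta, self.n)


@dataclass
class OriginReport:
    """Allele origins and per-family superior-allele frequencies."""

    table: pd.DataFrame  # one row per significant SNP
    family_freq: pd.DataFrame  # families x SNPs superior-allele frequencies


@dataclass
class ValidationResult:
    trait: str
    r: float
    n: int


# ---------------------------------------------------------------------------
# LD


def ld_pairwise(ms: MarkerSet, chromosome, max_pairs: int | None = None,
                seed: int | None = None) -> pd.DataFrame:
    """(distance bp, r^2) for marker pairs on one chromosome.

    r^2 is the squared Pearson correlation between dosage columns;
    ``max_pairs`` triggers seeded subsampling for dense chromosomes.
    """
    idx = np.where(ms.map["chrom"] == chromosome)[0]
    if idx.size < 2:
        return pd.DataFrame(columns=["dist", "r2"])
    X = ms.calls[:, idx]
    if not np.isfinite(X).all():
        raise ValueError("impute missing calls before LD computation")
    pos = ms.map["pos"].to_numpy()[idx]
    k = idx.size
    ii, jj = np.triu_indices(k, 1)
    if max_pairs is not None and ii.size > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(ii.size, size=max_pairs, replace=False)
        ii, jj = ii[sel], jj[sel]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    keep = (sd[ii] > 0) & (sd[jj] > 0)
    ii, jj = ii[keep], jj[keep]
    corr = np.einsum("ni,ni->i", Xc[:, ii], Xc[:, jj]) / (len(X) * sd[ii] * sd[jj])
    return pd.DataFrame({"dist": np.abs(pos[jj] - pos[ii]).astype(float), "r2": corr**2})


def hill_weir_expectation(distance, beta, n):
    """Drift expectation of r^2 at recombination intensity C = beta * distance."""
    C = beta * np.asarray(distance, dtype=float)
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return lead * corr


class LdDecayCurve(BaseEstimator):
    """Nonlinear least-squares fit of the Hill-Weir decay expectation.

    Parameters: ``n`` — the sample size entering the finite-sample
    correction term.  Fitted attributes: ``beta_``, ``half_decay_bp_``.
    """

    def __init__(self, n: int = 100):
        self.n = n

    def fit(self, distance, r2):
        d = np.asarray(distance, dtype=float)
        r2 = np.asarray(r2, dtype=float)
        if d.size < 10:
            raise ValueError("need at least 10 marker pairs to fit LD decay")

        def f(x, beta):
            return hill_weir_expectation(x, beta, self.n)

        scale = max(np.median(d), 1.0)
        try:
            popt, _ = optimize.curve_fit(
                f, d, r2, p0=[1.0 / scale], bounds=(0.0, np.inf), maxfev=10000
            )
        except RuntimeError as exc:
            resid = r2 - f(d, 1.0 / scale)
            raise RuntimeError(
                f"LD decay fit did not converge (residual sd {resid.std():.3g})"
            ) from exc
        self.beta_ = float(popt[0])
        e0 = float(f(0.0, self.beta_))
        if self.beta_ <= 0 or f(d.max() * 1e3, self.beta_) > e0 / 2.0:
            self.half_decay_bp_ = np.inf
        else:
            sol = optimize.brentq(lambda x: f(x, self.beta_) - e0 / 2.0, 0.0, d.max() * 1e3)
            self.half_decay_bp_ = float(sol)
        return self


def fit_ld_decay(pairs: pd.DataFrame, n: int) -> LdDecayFit:
    """Fit the decay curve to a (dist, r2) pair table."""
    model = LdDecayCurve(n=n).fit(pairs["dist"], pairs["r2"])
    return LdDecayFit(beta=model.beta_, n=n, pairs=pd.DataFrame(pairs),
                      half_decay_bp=model.half_decay_bp_)


# ---------------------------------------------------------------------------
# allele origin


def allele_origin(scan, ms: MarkerSet, recurrent, snps=None) -> OriginReport:
    """Trace significant-SNP alleles to the landrace donors or the recurrent parent.

    ``recurrent`` is the recurrent parent's dosage vector aligned to
    ``ms`` markers (homozygous: 0 or 2; heterozygous SNPs are flagged and
    their origin left undefined).  ``snps`` defaults to
    ``scan.significant`` (or all scan SNPs when no threshold was set).
    The superior allele is alt when the substitution effect is positive,
    ref when negative.
    """
    recurrent = np.asarray(recurrent, dtype=float)
    if recurrent.shape != (ms.n_markers,):
        raise ValueError("recurrent parent vector not aligned to markers")
    if snps is None:
        snps = scan.significant or list(scan.snp)
    name_to_col = {n: j for j, n in enumerate(ms.names)}
    scan_index = {n: j for j, n in enumerate(scan.snp)}
    families = sorted({f for f in ms.family if f not in ("check", "parent")})
    fam_rows = {f: [i for i, x in enumerate(ms.family) if x == f] for f in families}
    empty = [f for f in families if not fam_rows[f]]
    if empty:
        warnings.warn(f"families with zero lines excluded: {empty}")
        families = [f for f in families if fam_rows[f]]

    rows = []
    freq = {}
    for s in snps:
        j = name_to_col[s]
        eff = float(scan.effects[scan_index[s]])
        rp = recurrent[j]
        map_row = ms.map.iloc[j]
        if rp not in (0.0, 2.0):
            rows.append({"snp": s, "recurrent_dosage": rp, "landrace_allele": None,
                         "superior_allele": None, "superior_origin": "undefined",
                         "effect": eff})
            continue
        landrace_allele = "alt" if rp == 0.0 else "ref"
        superior_allele = "alt" if eff > 0 else "ref"
        origin = "landrace" if superior_allele == landrace_allele else "recurrent"
        rows.append({
            "snp": s,
            "recurrent_dosage": rp,
            "landrace_allele": map_row["alt"] if landrace_allele == "alt" else map_row["ref"],
            "superior_allele": map_row["alt"] if superior_allele == "alt" else map_row["ref"],
            "superior_origin": origin,
            "effect": eff,
        })
        col = {}
        for f in families:
            p_alt = float(np.mean(ms.calls[fam_rows[f], j])) / 2.0
            col[f] = p_alt if superior_allele == "alt" else 1.0 - p_alt
        freq[s] = col
    table = pd.DataFrame(rows)
    family_freq = pd.DataFrame(freq, index=families) if freq else pd.DataFrame(index=families)
    return OriginReport(table=table, family_freq=family_freq)


def rank_families(report: OriginReport, mode: str = "general") -> pd.DataFrame:
    """Rank families by ascending rank-sum of superior-allele frequencies.

    ``general`` uses every SNP with a defined superior allele;
    ``landrace_origin`` only SNPs whose superior allele is landrace
    derived.  Per SNP, rank 1 is the highest frequency; ties get the
    average rank.
    """
    if mode not in ("general", "landrace_origin"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    tab = report.table
    qual = tab[tab["superior_origin"] != "undefined"]
    if mode == "landrace_origin":
        qual = qual[qual["superior_origin"] == "landrace"]
    snps = [s for s in qual["snp"] if s in report.family_freq.columns]
    if not snps:
        raise ValueError(f"no qualifying SNPs for ranking mode '{mode}'")
    F = report.family_freq[snps]
    ranks = F.apply(lambda col: stats.rankdata(-col.to_numpy(), method="average"), axis=0)
    ranks.index = F.index
    out = pd.DataFrame({"rank_sum": ranks.sum(axis=1)})
    out["rank"] = stats.rankdata(out["rank_sum"], method="average")
    return out.sort_values("rank_sum")


# ---------------------------------------------------------------------------
# cross-generation validation


def predict_generation(effects: pd.Series, ms2: MarkerSet) -> pd.Series:
    """Predicted genetic values: significant-SNP dosages times BC1S1 effects.

    No intercept is added (the downstream Pearson correlation is
    location/scale invariant).
    """
    effects = pd.Series(effects)
    missing = [s for s in effects.index if s not in set(ms2.names)]
    if missing:
        raise KeyError(f"SNPs absent from the next-generation MarkerSet: {missing}")
    cols = [ms2.names.index(s) for s in effects.index]
    yhat = ms2.calls[:, cols] @ effects.to_numpy()
    return pd.Series(yhat, index=ms2.samples, name="yhat2")


def validate_prediction(yhat2: pd.Series, y2: pd.Series, trait: str = "trait") -> ValidationResult:
    """Pearson correlation between predicted values and observed BLUPs."""
    yhat2, y2 = pd.Series(yhat2), pd.Series(y2)
    common = yhat2.index.intersection(y2.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned genotypes for validation")
    a = yhat2.loc[common].to_numpy(dtype=float)
    b = y2.loc[common].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in predictions or observations; correlation undefined")
        return ValidationResult(trait=trait, r=float("nan"), n=len(common))
    r, _ = stats.pearsonr(a, b)
    return ValidationResult(trait=trait, r=float(r), n=len(common))
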