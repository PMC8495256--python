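"""Backcross introgression genotypes and multi-site two-treatment trial simulator.

The generator mirrors the structure of an early-testcross landrace
introgression programme: 20 heterogeneous landrace donor populations are
crossed to a single homozygous recurrent parent, backcrossed once
(expected donor-genome fraction 25%), selfed to BC1S1/BC1S2, and the
testcrosses evaluated at 3 sites under well-watered (WW, unreplicated
augmented design with knight-move check plots) and drought (DR, RCBD with
2 replicates) irrigation treatments with a sparse genotype-to-site
allocation.  Plot error is AR1(rho_col) x AR1(rho_row) spatially
correlated plus an independent nugget.

Every operation is deterministic under a fixed seed, and a truth record
(genetic values, variance components, QTL effects, true HMRP) accompanies
the simulated data for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MAP_COLUMNS, MarkerSet

__all__ = [
    "BreedingScenario",
    "TrialScenario",
    "TruthFile",
    "simulate_backcross_genotypes",
    "select_and_advance",
    "simulate_trials",
]

SITES = ("TL", "LM", "SI")
# WW check-plot fractions observed per site in the study design
CHECK_FRACTION = {"TL": 0.137, "LM": 0.117, "SI": 0.204}


@dataclass
class BreedingScenario:
    """Configuration of the introgression breeding scheme.

    Defaults are the study conditions: 20 landrace families, 1480 BC1F1
    lines (74 per family), 10 chromosomes, uniform 1 cM = 1 Mb scaling.
    Landraces are modelled as allele-frequency pools (heterogeneous
    populations) with per-marker founder frequencies drawn from a
    U(0.1, 0.9) hyper-prior.
    """

    n_families: int = 20
    lines_per_family: int = 74
    n_chromosomes: int = 10
    markers_per_chromosome: int = 30
    chrom_length_cm: float = 150.0
    cm_per_mb: float = 1.0
    founder_freq_low: float = 0.1
    founder_freq_high: float = 0.9
    recurrent_alt_fraction: float = 0.5
    qtl: list = field(default_factory=list)  # (marker index, alpha Mg/ha, {"DR","WW","both"})
    polygenic_var: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_chromosome < 2:
            raise ValueError("markers_per_chromosome must be >= 2 to model linkage")
        for j, a, trt in self.qtl:
            if not np.isfinite(a):
                raise ValueError("QTL effects must be finite")
            if trt not in ("DR", "WW", "both"):
                raise ValueError(f"QTL treatment specificity {trt!r} invalid")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass
class TrialScenario:
    """Configuration of the multi-site, two-treatment testcross trials.

    Defaults mirror the TC1 study layout: sites TL/LM/SI, sparse
    allocation groups (266 TL-only, 266 LM-only, 265 TL+LM, 529 all
    sites), augmented WW designs with site-specific check percentages
    arranged in a knight-move pattern, RCBD drought trials with 2
    replicates, and AR1xAR1-correlated plot error plus a nugget.
    """

    sites: tuple = SITES
    allocation: tuple = (266, 266, 265, 529)
    check_fraction: dict = field(default_factory=lambda: dict(CHECK_FRACTION))
    check_names: tuple = ("genetic_check", "CEBU", "P3055W", "P4082W")
    dr_replicates: int = 2
    dr_unreplicated_sites: tuple = ()
    n_columns: int | None = None  # None -> near-square field
    site_mean: dict = field(default_factory=lambda: {"TL": 6.0, "LM": 6.5, "SI": 5.5})
    drought_penalty: float = 2.5  # Mg/ha yield reduction under DR
    gxs_var: float = 0.05
    rho_row: float = 0.4
    rho_col: float = 0.4
    sigma2_spatial: float = 0.6
    sigma2_nugget: float = 0.3
    seed: int = 0


@dataclass
class TruthFile:
    """Simulation ground truth for parameter-recovery checks."""

    qtl: list
    genetic_values: pd.DataFrame | None = None  # genotype x site x treatment
    variance_components: dict = field(default_factory=dict)
    hmrp: pd.DataFrame | None = None  # true HMRP per genotype x site
    donor_fraction: np.ndarray | None = None
    scenario_seed: int | None = None


# ---------------------------------------------------------------------------
# meiosis machinery


def _recomb_fractions(sc: BreedingScenario) -> np.ndarray:
    """Haldane recombination fractions between adjacent markers (per chrom)."""
    cm = np.linspace(0.0, sc.chrom_length_cm, sc.markers_per_chromosome)
    d = np.diff(cm)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _meiose(hap_a: np.ndarray, hap_b: np.ndarray, sc: BreedingScenario, rng) -> np.ndarray:
    """One gamete per individual from haplotype pair arrays (n, m).

    A Markov walk along the map: the transmitted strand starts at random
    and switches between the two parental strands with the Haldane
    recombination fraction at each marker interval, independently per
    chromosome.
    """
    n, m = hap_a.shape
    k = sc.markers_per_chromosome
    r = _recomb_fractions(sc)
    strand = np.empty((n, m), dtype=bool)
    for c in range(sc.n_chromosomes):
        s = rng.random(n) < 0.5
        switches = rng.random((n, k - 1)) < r
        # cumulative XOR of switch indicators gives the strand path
        path = np.logical_xor.accumulate(np.column_stack([s, switches]), axis=1)
        strand[:, c * k : (c + 1) * k] = path
    return np.where(strand, hap_b, hap_a)


def simulate_backcross_genotypes(sc: BreedingScenario):
    """Simulate BC1S1 genotypes for all families.

    For each line: a landrace gamete is produced by meiosis from two
    haplotypes drawn from the family's founder allele frequencies; the F1
    (landrace gamete + recurrent gamete) is backcrossed to the recurrent
    parent, and the BC1F1 selfed once to give the BC1S1 line.  Expected
    donor-genome fraction is 0.25.

    Returns ``(MarkerSet, TruthFile)``; the MarkerSet carries phased
    haplotypes for downstream selfing, and the truth file the realized
    donor fraction per line.
    """
    rng = np.random.default_rng(sc.seed)
    m = sc.n_markers
    founder_freq = rng.uniform(sc.founder_freq_low, sc.founder_freq_high, size=(sc.n_families, m))
    recurrent_hap = (rng.random(m) < sc.recurrent_alt_fraction).astype(np.int8)

    n = sc.n_families * sc.lines_per_family
    fam_idx = np.repeat(np.arange(sc.n_families), sc.lines_per_family)
    p = founder_freq[fam_idx]

    # landrace parent haplotype pair, then its gamete
    land_a = (rng.random((n, m)) < p).astype(np.int8)
    land_b = (rng.random((n, m)) < p).astype(np.int8)
    land_gamete = _meiose(land_a, land_b, sc, rng)
    # track donor origin through the same crosses: origin=1 on landrace strands
    ones = np.ones((n, m), dtype=np.int8)
    zeros = np.zeros((n, m), dtype=np.int8)

    rec = np.broadcast_to(recurrent_hap, (n, m))
    # F1 = landrace gamete / recurrent; BC1F1 = F1 gamete / recurrent
    f1_a, f1_b = land_gamete, rec
    f1_oa, f1_ob = ones, zeros
    bc1_a, bc1_oa = _meiose_tracked(f1_a, f1_oa, f1_b, f1_ob, sc, rng)
    bc1_b, bc1_ob = rec, zeros
    # self BC1F1 -> BC1S1 (two gametes from the same plant)
    g1 = _meiose_tracked(bc1_a, bc1_oa, bc1_b, bc1_ob, sc, rng)
    g2 = _meiose_tracked(bc1_a, bc1_oa, bc1_b, bc1_ob, sc, rng)
    haps = np.stack([g1[0], g2[0]], axis=1)
    origins = np.stack([g1[1], g2[1]], axis=1)

    families = [f"FAM{f + 1:02d}" for f in fam_idx]
    samples = [f"{families[i]}_L{(i % sc.lines_per_family) + 1:03d}" for i in range(n)]
    map_df = _build_map(sc)
    ms = MarkerSet(
        samples=samples,
        family=families,
        generation=["BC1S1"] * n,
        calls=haps.sum(axis=1).astype(float),
        map=map_df,
        haplotypes=haps,
    )
    truth = TruthFile(
        qtl=list(sc.qtl),
        donor_fraction=origins.mean(axis=(1, 2)),
        scenario_seed=sc.seed,
    )
    return ms, truth


def _meiose_tracked(hap_a, origin_a, hap_b, origin_b, sc, rng):
    """Meiosis applied jointly to allele and origin channels (same crossovers)."""
    n, m = hap_a.shape
    k = sc.markers_per_chromosome
    r = _recomb_fractions(sc)
    strand = np.empty((n, m), dtype=bool)
    for c in range(sc.n_chromosomes):
        s = rng.random(n) < 0.5
        switches = rng.random((n, k - 1)) < r
        path = np.logical_xor.accumulate(np.column_stack([s, switches]), axis=1)
        strand[:, c * k : (c + 1) * k] = path
    allele = np.where(strand, hap_b, hap_a)
    origin = np.where(strand, origin_b, origin_a)
    return allele, origin


def _build_map(sc: BreedingScenario) -> pd.DataFrame:
    k = sc.markers_per_chromosome
    cm = np.linspace(0.0, sc.chrom_length_cm, k)
    pos = np.maximum(1, np.round(cm / sc.cm_per_mb * 1e6).astype(int))
    rows = []
    i = 0
    for c in range(1, sc.n_chromosomes + 1):
        for j in range(k):
            i += 1
            rows.append((f"M{i}", c, int(pos[j]) + j, "A", "G"))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def select_and_advance(
    ms: MarkerSet,
    selected_ids,
    ears_per_line: float = 174 / 64,
    seed: int | None = None,
) -> MarkerSet:
    """Self selected BC1S1 lines one generation to produce BC1S2 lines.

    Each selected line contributes 2-3 ears (progeny lines); the total is
    ``round(n_selected * ears_per_line)`` with the extra third ears
    assigned to a seeded random subset of lines.  The default rate, 174/64,
    reflects the harvest recovery of the reference programme.
    """
    selected_ids = list(selected_ids)
    if not selected_ids:
        raise ValueError("empty selection")
    index = {s: i for i, s in enumerate(ms.samples)}
    missing = [s for s in selected_ids if s not in index]
    if missing:
        raise KeyError(f"selected IDs absent from MarkerSet: {missing[:5]}")
    rng = np.random.default_rng(seed)
    n_sel = len(selected_ids)
    total = int(round(n_sel * ears_per_line))
    base = total // n_sel
    extra = total - base * n_sel
    counts = np.full(n_sel, base, dtype=int)
    counts[rng.choice(n_sel, size=extra, replace=False)] += 1

    if ms.haplotypes is not None:
        haps = ms.haplotypes
    else:
        # unphased input: assign random phase at heterozygous sites
        calls = ms.calls
        het = calls == 1
        a = (calls >= 1).astype(np.int8)
        b = (calls == 2).astype(np.int8)
        flip = rng.random(calls.shape) < 0.5
        a2 = np.where(het & flip, 0, a)
        b2 = np.where(het & flip, 1, b)
        haps = np.stack([a2, b2], axis=1).astype(np.int8)

    # a throwaway breeding scenario carrying only the map geometry
    k = int((ms.map["chrom"] == ms.map["chrom"].iloc[0]).sum())
    sc = BreedingScenario(
        n_chromosomes=ms.map["chrom"].nunique(),
        markers_per_chromosome=k,
        seed=0,
    )
    rows_a, rows_b, samples, family, parent_rows = [], [], [], [], []
    for s_id, cnt in zip(selected_ids, counts):
        i = index[s_id]
        for e in range(cnt):
            parent_rows.append(i)
            samples.append(f"{s_id}_E{e + 1}")
            family.append(ms.family[i])
    parent_rows = np.array(parent_rows)
    pa = haps[parent_rows, 0, :]
    pb = haps[parent_rows, 1, :]
    g1 = _meiose(pa, pb, sc, rng)
    g2 = _meiose(pa, pb, sc, rng)
    new_haps = np.stack([g1, g2], axis=1)
    return MarkerSet(
        samples=samples,
        family=family,
        generation=["BC1S2"] * len(samples),
        calls=new_haps.sum(axis=1).astype(float),
        map=ms.map.copy(),
        haplotypes=new_haps,
    )


# ---------------------------------------------------------------------------
# field trials


def _field_dims(n_plots: int, n_columns: int | None):
    if n_columns is None:
        n_columns = max(1, int(math.ceil(math.sqrt(n_plots))))
    n_rows = int(math.ceil(n_plots / n_columns))
    return n_rows, n_columns


def _knight_positions(n_rows, n_cols, n_checks):
    """Successive (+1 row, +2 columns) placements wrapping over the grid."""
    pos, seen = [], set()
    r, c = 0, 0
    guard = 0
    while len(pos) < n_checks and guard < 4 * n_rows * n_cols:
        guard += 1
        if (r, c) not in seen:
            seen.add((r, c))
            pos.append((r, c))
        r2 = (r + 1) % n_rows
        c2 = (c + 2) % n_cols
        if (r2, c2) in seen:
            c2 = (c2 + 1) % n_cols
        r, c = r2, c2
    return pos


def _spatial_error(n_rows, n_cols, ts: TrialScenario, rng) -> np.ndarray:
    from .spatial import ar1_correlation

    lr = np.linalg.cholesky(ar1_correlation(n_rows, ts.rho_row))
    lc = np.linalg.cholesky(ar1_correlation(n_cols, ts.rho_col))
    z = rng.standard_normal((n_rows, n_cols))
    zeta = math.sqrt(ts.sigma2_spatial) * (lr @ z @ lc.T)
    eta = math.sqrt(ts.sigma2_nugget) * rng.standard_normal((n_rows, n_cols))
    return zeta + eta


def _allocate_sites(ms_samples, families, ts: TrialScenario, rng):
    """Sparse allocation of test genotypes to site groups, balanced by family.

    Groups (with the 3-site default): site1-only, site2-only, sites 1+2,
    all sites.  Returns ``{site: [genotype ids]}``.
    """
    n_groups = len(ts.allocation)
    total = sum(ts.allocation)
    if total > len(ms_samples):
        raise ValueError(f"allocation requires {total} genotypes, MarkerSet has {len(ms_samples)}")
    chosen = list(ms_samples[:total])
    # round-robin by family for ancestry balance within groups
    by_fam = {}
    for s, f in zip(chosen, families[: len(chosen)]):
        by_fam.setdefault(f, []).append(s)
    order = []
    fams = sorted(by_fam)
    for f in fams:
        rng.shuffle(by_fam[f])
    while any(by_fam.values()):
        for f in fams:
            if by_fam[f]:
                order.append(by_fam[f].pop())
    groups, i = [], 0
    for g in ts.allocation:
        groups.append(order[i : i + g])
        i += g
    s1, s2, s3 = ts.sites[:3]
    site_map = {s1: [], s2: [], s3: []}
    group_sites = [(s1,), (s2,), (s1, s2), ts.sites]
    for members, sites in zip(groups, group_sites[: n_groups]):
        for s in sites:
            site_map[s].extend(members)
    return site_map


def simulate_trials(ms: MarkerSet, ts: TrialScenario, sc: BreedingScenario):
    """Simulate the plot-level yield table for all site x treatment trials.

    Plot yield = site/treatment mean + testcross genetic value
    (sum over QTL of alpha * dosage / 2, plus a seeded polygenic term)
    + genotype-by-site deviation + AR1xAR1 spatial error + nugget.
    WW trials are unreplicated with knight-move check plots; DR trials are
    RCBDs with ``dr_replicates`` contiguous blocks.

    Returns ``(plots DataFrame, TruthFile)``.
    """
    rng = np.random.default_rng(ts.seed)
    site_map = _allocate_sites(ms.samples, ms.family, ts, rng)
    all_geno = sorted({g for v in site_map.values() for g in v})
    idx = {s: i for i, s in enumerate(ms.samples)}

    # genetic values per treatment
    qtl_val = {"WW": np.zeros(len(all_geno)), "DR": np.zeros(len(all_geno))}
    dos = ms.calls[[idx[g] for g in all_geno]]
    for j, alpha, trt in sc.qtl:
        contrib = alpha * dos[:, j] / 2.0
        for t in ("WW", "DR"):
            if trt in (t, "both"):
                qtl_val[t] += contrib
    poly = rng.normal(0.0, math.sqrt(sc.polygenic_var), size=len(all_geno))
    gval = {t: qtl_val[t] + poly for t in ("WW", "DR")}
    gpos = {g: i for i, g in enumerate(all_geno)}

    gxs = {
        (g, s): rng.normal(0.0, math.sqrt(ts.gxs_var))
        for s in ts.sites
        for g in site_map[s]
    }

    records = []
    for site in ts.sites:
        entries = list(site_map[site])
        rng.shuffle(entries)
        for trt in ("WW", "DR"):
            mean = ts.site_mean.get(site, 6.0) - (ts.drought_penalty if trt == "DR" else 0.0)
            unreplicated = trt == "WW" or site in ts.dr_unreplicated_sites
            if unreplicated:
                frac = ts.check_fraction.get(site, 0.15)
                n_test = len(entries)
                n_plots = int(math.ceil(n_test / (1.0 - frac)))
                n_checks = n_plots - n_test
                n_rows, n_cols = _field_dims(n_plots, ts.n_columns)
                check_pos = set(_knight_positions(n_rows, n_cols, n_checks))
                err = _spatial_error(n_rows, n_cols, ts, rng)
                test_iter = iter(entries)
                check_cycle = 0
                placed = 0
                for col in range(n_cols):
                    for row in range(n_rows):
                        if placed >= n_plots:
                            break
                        if (row, col) in check_pos:
                            g = ts.check_names[check_cycle % len(ts.check_names)]
                            check_cycle += 1
                            gv = 0.0
                            is_check = True
                        else:
                            try:
                                g = next(test_iter)
                            except StopIteration:
                                continue
                            gv = gval[trt][gpos[g]] + gxs[(g, site)]
                            is_check = False
                        records.append(
                            (site, trt, row + 1, col + 1, 1, g, is_check, mean + gv + err[row, col])
                        )
                        placed += 1
            else:
                reps = ts.dr_replicates
                n_test = len(entries)
                n_plots = n_test * reps
                n_rows, n_cols = _field_dims(n_plots, ts.n_columns)
                err = _spatial_error(n_rows, n_cols, ts, rng)
                # blocks are contiguous column spans of the field
                plot_i = 0
                for rep in range(1, reps + 1):
                    order = list(entries)
                    rng.shuffle(order)
                    for g in order:
                        row = plot_i % n_rows
                        col = plot_i // n_rows
                        gv = gval[trt][gpos[g]] + gxs[(g, site)]
                        records.append(
                            (site, trt, row + 1, col + 1, rep, g, False, mean + gv + err[row, col])
                        )
                        plot_i += 1
    plots = pd.DataFrame(
        records,
        columns=["site", "treatment", "row", "col", "rep", "entry", "is_check", "yield"],
    )

    gv_rows = []
    hmrp_rows = []
    for site in ts.sites:
        mean_ww = ts.site_mean.get(site, 6.0)
        mean_dr = mean_ww - ts.drought_penalty
        site_true_ww = np.array([mean_ww + gval["WW"][gpos[g]] + gxs[(g, site)] for g in site_map[site]])
        site_true_dr = np.array([mean_dr + gval["DR"][gpos[g]] + gxs[(g, site)] for g in site_map[site]])
        mu_ww, mu_dr = site_true_ww.mean(), site_true_dr.mean()
        for g, vww, vdr in zip(site_map[site], site_true_ww, site_true_dr):
            gv_rows.append((g, site, "WW", vww))
            gv_rows.append((g, site, "DR", vdr))
            rw, rd = vww / mu_ww, vdr / mu_dr
            if rw > 0 and rd > 0:
                hmrp_rows.append((g, site, 2.0 / (1.0 / rw + 1.0 / rd)))
    truth = TruthFile(
        qtl=list(sc.qtl),
        genetic_values=pd.DataFrame(gv_rows, columns=["entry", "site", "treatment", "value"]),
        variance_components={
            "polygenic_var": sc.polygenic_var,
            "gxs_var": ts.gxs_var,
            "sigma2_spatial": ts.sigma2_spatial,
            "sigma2_nugget": ts.sigma2_nugget,
            "rho_row": ts.rho_row,
            "rho_col": ts.rho_col,
        },
        hmrp=pd.DataFrame(hmrp_rows, columns=["entry", "site", "hmrp"]),
        scenario_seed=ts.seed,
    )
    return plots, truth
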