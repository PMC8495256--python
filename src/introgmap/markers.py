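"""Genotype data model, file I/O, quality control, imputation and window queries.

The central container is :class:`MarkerSet`: a samples x markers matrix of
alternative-allele dosages (0, 1, 2, or missing before imputation) together
with a physical map, per-sample landrace-family labels and a generation label.
Marker names follow genome order ("M1" is the first marker on chromosome 1).

The canonical on-disk dialect is a pair of CSV files: a calls table
(``sample, family, generation, M1, M2, ...``) and a map table
(``name, chrom, pos, ref, alt``).  A VCF reader is provided as a convenience;
coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSet",
    "QcReport",
    "GeneWindowHit",
    "read_marker_table",
    "write_marker_table",
    "filter_markers",
    "impute_wright",
    "snp_density",
    "annotate_windows",
]

MAP_COLUMNS = ["name", "chrom", "pos", "ref", "alt"]


@dataclass
class MarkerSet:
    """Dosage-coded genotypes with a physical map and sample metadata.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers.
    family : list of str
        Per-sample landrace-family label (a donor population name, or
        ``"check"`` / ``"parent"``).
    generation : list of str
        Per-sample generation label (``BC1S1``, ``BC1S2`` or ``founder``).
    calls : ndarray, shape (n_samples, n_markers)
        Alternative-allele dosage.  Before imputation entries are in
        {0, 1, 2} with ``nan`` for missing; after imputation real values in
        [0, 2] with no missing.
    map : DataFrame
        One row per marker with columns ``name, chrom, pos, ref, alt``,
        sorted by (chrom, pos); positions are 1-based base pairs.
    haplotypes : ndarray or None, shape (n_samples, 2, n_markers)
        Optional phased 0/1 alt-allele haplotypes, populated by the
        simulator; used by the selfing generator when present.
    """

    samples: list
    family: list
    generation: list
    calls: np.ndarray
    map: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x markers array")
        n, m = self.calls.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} samples for {n} call rows")
        if len(self.family) != n or len(self.generation) != n:
            raise ValueError("family/generation must match sample count")
        if len(set(self.samples)) != n:
            raise ValueError("sample IDs must be unique")
        if len(self.map) != m:
            raise ValueError(f"map has {len(self.map)} rows for {m} markers")
        missing_cols = set(MAP_COLUMNS) - set(self.map.columns)
        if missing_cols:
            raise ValueError(f"map is missing columns {sorted(missing_cols)}")
        order = np.lexsort((self.map["pos"].to_numpy(), self.map["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(m)):
            warnings.warn("marker map was not sorted by (chrom, pos); sorting")
            self.map = self.map.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]
            if self.haplotypes is not None:
                self.haplotypes = self.haplotypes[:, :, order]
        else:
            self.map = self.map.reset_index(drop=True)
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def names(self) -> list:
        return self.map["name"].tolist()

    def alt_frequency(self) -> np.ndarray:
        """Observed alternative-allele frequency per marker (missing ignored)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.calls, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return np.isfinite(self.calls).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def take_markers(self, idx: np.ndarray) -> "MarkerSet":
        idx = np.asarray(idx)
        return MarkerSet(
            samples=list(self.samples),
            family=list(self.family),
            generation=list(self.generation),
            calls=self.calls[:, idx].copy(),
            map=self.map.iloc[idx].reset_index(drop=True),
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx].copy(),
        )

    def take_samples(self, idx: Iterable[int]) -> "MarkerSet":
        idx = list(idx)
        return MarkerSet(
            samples=[self.samples[i] for i in idx],
            family=[self.family[i] for i in idx],
            generation=[self.generation[i] for i in idx],
            calls=self.calls[idx].copy(),
            map=self.map.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx].copy(),
        )

    def equals(self, other: "MarkerSet") -> bool:
        return (
            self.samples == other.samples
            and self.family == other.family
            and self.generation == other.generation
            and np.allclose(self.calls, other.calls, equal_nan=True)
            and self.map.reset_index(drop=True).equals(other.map.reset_index(drop=True))
        )


@dataclass
class QcReport:
    """Accounting of a marker-filtering pass.

    The MAF test is applied first: a marker failing both thresholds is
    counted once, under ``n_removed_maf``.
    """

    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_retained: int
    maf: np.ndarray = field(repr=False)
    call_rate: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.n_input != self.n_removed_maf + self.n_removed_callrate + self.n_retained:
            raise ValueError("QC categories do not sum to marker input count")

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_removed_maf": int(self.n_removed_maf),
            "n_removed_callrate": int(self.n_removed_callrate),
            "n_retained": int(self.n_retained),
        }


@dataclass
class GeneWindowHit:
    """A gene whose span intersects the window centred on a SNP."""

    snp: str
    gene_id: str
    chrom: object
    start: int
    end: int
    distance: int


# ---------------------------------------------------------------------------
# I/O


def _parse_calls_frame(df: pd.DataFrame, map_df: pd.DataFrame, path) -> MarkerSet:
    meta_cols = ["sample", "family", "generation"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"{path}: calls table lacks required column '{c}'")
    marker_cols = [c for c in df.columns if c not in meta_cols]
    if list(map_df["name"]) != marker_cols:
        # allow map to define order; calls columns reordered to match
        missing = set(map_df["name"]) - set(marker_cols)
        if missing:
            raise ValueError(f"{path}: markers {sorted(missing)[:5]}... absent from calls")
        df = df[meta_cols + list(map_df["name"])]
        marker_cols = list(map_df["name"])
    raw = df[marker_cols].to_numpy()
    calls = np.full(raw.shape, np.nan)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() in ("", "NA", "."):
                continue
            try:
                x = float(v)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: unparseable dosage '{v}' at row {i + 2}, marker {marker_cols[j]}")
            if x not in (0.0, 1.0, 2.0) and not (0.0 <= x <= 2.0):
                raise ValueError(f"{path}: dosage {x} out of range at row {i + 2}, marker {marker_cols[j]}")
            calls[i, j] = x
    return MarkerSet(
        samples=df["sample"].astype(str).tolist(),
        family=df["family"].astype(str).tolist(),
        generation=df["generation"].astype(str).tolist(),
        calls=calls,
        map=map_df[MAP_COLUMNS].copy(),
    )


def read_marker_table(path, format: str = "csv", map_path=None) -> MarkerSet:
    """Read a :class:`MarkerSet` from disk.

    ``format="csv"`` reads the canonical calls/map CSV pair (``map_path``
    defaults to ``<stem>.map.csv`` next to ``path``).  ``format="vcf"``
    reads genotypes from a VCF, converting each record to alt-allele dosage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        if map_path is None:
            map_path = path.with_suffix("").with_suffix("")  # strip once
            map_path = path.parent / (path.stem + ".map.csv")
        map_path = Path(map_path)
        if not map_path.exists():
            raise FileNotFoundError(f"marker map file {map_path} not found")
        map_df = pd.read_csv(map_path)
        missing = set(MAP_COLUMNS) - set(map_df.columns)
        if missing:
            raise ValueError(f"{map_path}: map lacks columns {sorted(missing)}")
        df = pd.read_csv(path, dtype={"sample": str, "family": str, "generation": str})
        return _parse_calls_frame(df, map_df, path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path) -> MarkerSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, names, chroms, poss, refs, alts = [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        alt = rec.ALT[0] if rec.ALT else "."
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 gt_types uses 3 for unknown)
        ds = np.array([sum(a > 0 for a in g[:2]) if g[0] >= 0 else np.nan for g in rec.genotypes], dtype=float)
        rows.append(ds)
        names.append(rec.ID if rec.ID not in (None, ".") else f"M{i + 1}")
        chrom = rec.CHROM.removeprefix("chr")
        chroms.append(int(chrom) if str(chrom).isdigit() else chrom)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(alt)
    calls = np.array(rows).T if rows else np.empty((len(samples), 0))
    map_df = pd.DataFrame({"name": names, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    n = len(samples)
    return MarkerSet(
        samples=samples,
        family=["unknown"] * n,
        generation=["founder"] * n,
        calls=calls,
        map=map_df,
    )


def write_marker_table(ms: MarkerSet, path, map_path=None) -> None:
    """Write the canonical CSV pair (calls + map)."""
    path = Path(path)
    if map_path is None:
        map_path = path.parent / (path.stem + ".map.csv")
    df = pd.DataFrame({"sample": ms.samples, "family": ms.family, "generation": ms.generation})
    calls = pd.DataFrame(ms.calls, columns=ms.names)
    pd.concat([df, calls], axis=1).to_csv(path, index=False)
    ms.map[MAP_COLUMNS].to_csv(map_path, index=False)


# ---------------------------------------------------------------------------
# Quality control and imputation


def filter_markers(ms: MarkerSet, maf_min: float = 0.05, callrate_min: float = 0.95):
    """Remove markers with MAF < ``maf_min`` or call rate < ``callrate_min``.

    Returns ``(filtered MarkerSet, QcReport)``.  The MAF test is applied
    first, so a marker failing both thresholds is counted under MAF.
    """
    maf = ms.maf()
    cr = ms.call_rate()
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= maf_min)  # nan (all-missing) counts as MAF failure
        fail_cr = ~fail_maf & (cr < callrate_min)
    keep = ~fail_maf & ~fail_cr
    report = QcReport(
        n_input=ms.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int(fail_cr.sum()),
        n_retained=int(keep.sum()),
        maf=maf,
        call_rate=cr,
    )
    if report.n_retained == 0:
        warnings.warn("no markers retained after QC (monomorphic or low-quality input)")
    return ms.take_markers(np.where(keep)[0]), report


def impute_wright(ms: MarkerSet, mode: str = "expectation", seed: int | None = None) -> MarkerSet:
    """Impute missing dosages from per-marker allele frequencies.

    ``expectation`` replaces a missing call at marker *k* by ``2 p_k`` where
    ``p_k`` is the observed alt frequency (deterministic).  ``sample`` draws
    a genotype from Hardy–Weinberg probabilities ``(q^2, 2pq, p^2)`` with
    the given seed.
    """
    if mode not in ("expectation", "sample"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    calls = ms.calls.copy()
    missing = ~np.isfinite(calls)
    if not missing.any():
        return replace(ms, calls=calls)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = [ms.names[j] for j in np.where(all_missing)[0][:5]]
        raise ValueError(f"markers with no observed calls (filter first): {bad}")
    p = ms.alt_frequency()
    if mode == "expectation":
        fill = np.broadcast_to(2.0 * p, calls.shape)
        calls[missing] = fill[missing]
    else:
        rng = np.random.default_rng(seed)
        probs = np.column_stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        for j in np.where(missing.any(axis=0))[0]:
            rows = np.where(missing[:, j])[0]
            calls[rows, j] = rng.choice(3, size=rows.size, p=probs[j])
    return replace(ms, calls=calls)


# ---------------------------------------------------------------------------
# Genome summaries


def snp_density(
    ms: MarkerSet,
    window_bp: float = 100e6,
    chromosomes: Sequence | None = None,
) -> dict:
    """Marker counts in non-overlapping windows starting at position 1.

    Returns ``{chrom: ndarray of counts}``.  Windows with zero markers are
    reported; a requested chromosome with no markers yields a single zero
    window.
    """
    window_bp = int(window_bp)
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if chromosomes is None:
        chromosomes = sorted(ms.map["chrom"].unique())
    out = {}
    for c in chromosomes:
        pos = ms.map.loc[ms.map["chrom"] == c, "pos"].to_numpy()
        if pos.size == 0:
            out[c] = np.zeros(1, dtype=int)
            continue
        n_windows = int((pos.max() - 1) // window_bp) + 1
        idx = (pos - 1) // window_bp
        out[c] = np.bincount(idx.astype(int), minlength=n_windows)
    return out


def annotate_windows(
    snps: Sequence[str],
    ms: MarkerSet,
    gff,
    halfwidth: int = 100_000,
) -> list:
    """Genes within ``halfwidth`` bp of each SNP (closed window, 1-based).

    Only features of type ``gene`` are considered; hits are sorted by
    distance (0 when the SNP lies inside the gene span).
    """
    import gffutils

    name_to_row = {n: i for i, n in enumerate(ms.map["name"])}
    for s in snps:
        if s not in name_to_row:
            raise KeyError(f"SNP {s!r} not present in the marker map")
    db = gffutils.create_db(
        str(gff), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    hits = []
    for s in snps:
        row = ms.map.iloc[name_to_row[s]]
        chrom, pos = row["chrom"], int(row["pos"])
        lo, hi = pos - halfwidth, pos + halfwidth
        for g in db.region(seqid=str(chrom), start=max(lo, 1), end=hi, featuretype="gene"):
            if g.end < lo or g.start > hi:
                continue
            if g.start <= pos <= g.end:
                dist = 0
            else:
                dist = min(abs(g.start - pos), abs(g.end - pos))
            gid = g.attributes.get("ID", [g.id])[0]
            hits.append(GeneWindowHit(snp=s, gene_id=gid, chrom=chrom, start=g.start, end=g.end, distance=dist))
    hits.sort(key=lambda h: (h.snp, h.distance, h.gene_id))
    return hits
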