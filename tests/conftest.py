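import numpy as np
import pandas as pd
import pytest

from introgmap.markers import MarkerSet
from introgmap.spatial import ar1_correlation


def make_marker_set(calls, chrom=None, pos=None, family=None, generation="BC1S1",
                    ref="A", alt="G"):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if chrom is None:
        chrom = [1] * m
    if pos is None:
        pos = list(range(1000, 1000 + 1000 * m, 1000))
    if family is None:
        family = ["FAM01"] * n
    mp = pd.DataFrame({
        "name": [f"M{j + 1}" for j in range(m)],
        "chrom": chrom, "pos": pos, "ref": [ref] * m, "alt": [alt] * m,
    })
    return MarkerSet(
        samples=[f"S{i + 1}" for i in range(n)],
        family=list(family),
        generation=[generation] * n,
        calls=calls,
        map=mp,
    )


def simulate_trial_plots(n_rows, n_cols, n_geno, rho_row, rho_col,
                         s2_spatial, s2_nugget, seed, geno_sd=0.7, mean=5.0,
                         row_trend=0.0, col_trend=0.0):
    """One rectangular trial with each genotype replicated over the grid."""
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    assert n % n_geno == 0
    entries = np.repeat(np.arange(n_geno), n // n_geno)
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
            y = mean + gv[g] + err[r, c] + row_trend * r + col_trend * c
            recs.append((r + 1, c + 1, f"G{g:03d}", y))
    plots = pd.DataFrame(recs, columns=["row", "col", "entry", "yield"])
    return plots, gv


@pytest.fixture
def tiny_marker_set():
    rng = np.random.default_rng(42)
    return make_marker_set(rng.binomial(2, 0.4, size=(12, 8)).astype(float))
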