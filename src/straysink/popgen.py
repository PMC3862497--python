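"""Summary statistics: allele frequencies, heterozygosities, pairwise
Weir-Cockerham F_ST, and exact tests of allelic differentiation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, Collection, CollectionSet

__all__ = [
    "allele_frequencies",
    "heterozygosities",
    "pairwise_fst",
    "differentiation_exact_test",
    "divergence_matrix",
]


def _freq_and_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(genotypes)
    ok = g != MISSING
    typed = ok.sum(axis=0)
    ref = np.where(ok, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(typed > 0, ref / (2.0 * typed), np.nan)
    return p, typed


def allele_frequencies(collection: Collection) -> pd.DataFrame:
    """Per-locus reference-allele frequency ``(2 n_AA + n_Aa) / (2 n_typed)``.

    Loci with no typed genotypes get a NaN estimate (flagged by
    ``typed == 0``).
    """
    p, typed = _freq_and_counts(collection.genotypes)
    return pd.DataFrame({"frequency": p, "n_typed": typed})


def heterozygosities(collection: Collection) -> pd.DataFrame:
    """Observed and (unbiased) expected heterozygosity per locus.

    ``Ho`` is the heterozygote fraction among typed fish; ``He`` is
    ``2 p (1-p) * 2n/(2n-1)`` (Nei's small-sample correction).  The
    attached ``.attrs`` carry the across-locus means.
    """
    g = collection.genotypes
    ok = g != MISSING
    typed = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(typed > 0, ((g == 1) & ok).sum(axis=0) / typed, np.nan)
    p, _ = _freq_and_counts(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = np.where(
            typed > 1, 2.0 * p * (1.0 - p) * (2.0 * typed) / (2.0 * typed - 1.0), np.nan
        )
    out = pd.DataFrame({"Ho": ho, "He": he, "n_typed": typed})
    out.attrs["mean_Ho"] = float(np.nanmean(ho))
    out.attrs["mean_He"] = float(np.nanmean(he))
    return out


def _wc_components(
    ga: np.ndarray, gb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-locus variance components a, b, c for
    two populations of diploids at a biallelic locus."""
    comps = []
    for g in (ga, gb):
        ok = g != MISSING
        n = ok.sum(axis=0).astype(float)
        ref = np.where(ok, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ref / (2.0 * n)
            h = ((g == 1) & ok).sum(axis=0) / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def pairwise_fst(coll_a: Collection, coll_b: Collection) -> float:
    """Multi-locus Weir-Cockerham theta between two collections.

    Per-locus variance components are combined as a ratio of sums across
    loci; loci monomorphic over both collections (zero denominator) drop
    out.  Negative estimates are reported as computed.
    """
    if coll_a.n_loci != coll_b.n_loci:
        raise ValueError("collections must share a locus panel")
    a, b, c = _wc_components(coll_a.genotypes, coll_b.genotypes)
    denom = a + b + c
    use = np.isfinite(denom) & (denom != 0.0)
    if not use.any():
        raise ValueError("no shared polymorphic loci")
    return float(a[use].sum() / denom[use].sum())


def differentiation_exact_test(
    coll_a: Collection, coll_b: Collection
) -> tuple[np.ndarray, float]:
    """Exact test of allelic differentiation between two collections.

    Per locus, Fisher's exact test on the 2x2 allele-count table; loci
    monomorphic in both collections are excluded; per-locus p-values are
    combined by Fisher's method.  Returns (per-locus p with NaN for
    excluded loci, combined p).
    """
    if coll_a.n_loci != coll_b.n_loci:
        raise ValueError("collections must share a locus panel")
    pvals = np.full(coll_a.n_loci, np.nan)
    for l in range(coll_a.n_loci):
        table = []
        for c in (coll_a, coll_b):
            g = c.genotypes[:, l]
            typed = g[g != MISSING]
            ref = int(typed.sum())
            table.append([ref, int(2 * typed.size - ref)])
        table = np.asarray(table)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue  # monomorphic in both, or one side empty
        pvals[l] = stats.fisher_exact(table, alternative="two-sided")[1]
    used = pvals[~np.isnan(pvals)]
    if used.size == 0:
        return pvals, 1.0
    combined = stats.combine_pvalues(used, method="fisher")[1]
    return pvals, float(combined)


def divergence_matrix(collections: CollectionSet) -> pd.DataFrame:
    """All-pairs divergence: F_ST below the diagonal, exact-test combined
    p-values above, mean He on the diagonal."""
    names = [c.name for c in collections]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, ca in enumerate(collections):
        out.iloc[i, i] = heterozygosities(ca).attrs["mean_He"]
        for j in range(i + 1, len(names)):
            cb = collections.collections[j]
            out.iloc[j, i] = pairwise_fst(ca, cb)
            out.iloc[i, j] = differentiation_exact_test(ca, cb)[1]
    return out
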