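"""Genotype quality control for archival and contemporary collections.

The pipeline removes, in order: otolith-marked strays and individuals
with excessive missing data; loci with poor coverage in historical
(archived-scale) collections; loci out of Hardy-Weinberg equilibrium in
a majority of collections (after sequential-Bonferroni correction within
each collection); invariant loci; and one locus from each pair in
linkage disequilibrium in more than half of the collections.  Two
contamination screens operate on individuals: a multi-allelic
(microsatellite) screen here, and the Bayesian genotype-frequency model
in :mod:`straysink.contamination`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, Collection, CollectionSet

__all__ = [
    "QcReport",
    "LocusPanel",
    "filter_individuals",
    "filter_loci",
    "hwe_exact_test",
    "sequential_bonferroni",
    "hwe_locus_screen",
    "ld_pair_test",
    "prune_linked_loci",
    "microsat_contamination_screen",
    "replicate_concordance",
]

#: Individual-removal reasons, in report-column order.
REASONS = ("stray", "missing", "microsat", "hwe_model")


@dataclass
class QcReport:
    """Per-collection accounting of individuals removed at each step."""

    initial: dict[str, int] = field(default_factory=dict)
    removed: dict[str, dict[str, int]] = field(default_factory=dict)

    def start(self, name: str, n: int) -> None:
        self.initial[name] = n
        self.removed.setdefault(name, {r: 0 for r in REASONS})

    def record(self, name: str, reason: str, n: int) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown removal reason {reason!r}")
        self.removed[name][reason] += n

    def final(self, name: str) -> int:
        return self.initial[name] - sum(self.removed[name].values())

    def balanced(self) -> bool:
        """Accounting identity: initial = removed + final, per collection."""
        return all(
            self.initial[n] == sum(self.removed[n].values()) + self.final(n)
            for n in self.initial
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.initial:
            row = {"collection": name, "initial_n": self.initial[name]}
            row.update(self.removed[name])
            row["final_n"] = self.final(name)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LocusPanel:
    """Per-locus retention status through the locus filters."""

    loci: list[str]
    status: dict[str, str] = field(default_factory=dict)        # name -> status
    heterozygosity: dict[str, float] = field(default_factory=dict)
    historical_missing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.loci:
            self.status.setdefault(name, "retained")

    def remove(self, name: str, why: str) -> None:
        if self.status[name] == "retained":
            self.status[name] = f"removed:{why}"

    @property
    def retained(self) -> list[str]:
        return [l for l in self.loci if self.status[l] == "retained"]

    def retained_mask(self) -> np.ndarray:
        return np.array([self.status[l] == "retained" for l in self.loci])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.loci,
                "status": [self.status[l] for l in self.loci],
                "heterozygosity": [self.heterozygosity.get(l, np.nan) for l in self.loci],
                "historical_missing": [
                    self.historical_missing.get(l, np.nan) for l in self.loci
                ],
            }
        )


def filter_individuals(
    collection: Collection, max_missing: float = 0.20
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Remove otolith-flagged strays and individuals with too much missing data.

    An individual is dropped when its missing fraction *strictly* exceeds
    ``max_missing`` (a fish missing exactly the threshold fraction is
    kept).  Returns the retained row indices, order preserved, and the
    removed ids grouped by reason.
    """
    if collection.n_individuals == 0:
        raise ValueError("empty collection")
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must lie in (0, 1)")
    miss_frac = (collection.genotypes == MISSING).mean(axis=1)
    stray = collection.stray
    too_missing = (miss_frac > max_missing) & ~stray
    keep = ~(stray | too_missing)
    removed = {
        "stray": [collection.ids[i] for i in np.flatnonzero(stray)],
        "missing": [collection.ids[i] for i in np.flatnonzero(too_missing)],
    }
    return np.flatnonzero(keep), removed


def filter_loci(
    collections: CollectionSet, panel: LocusPanel, min_typed: int = 55
) -> LocusPanel:
    """Locus coverage and invariance filters.

    A locus is removed if fewer than ``min_typed`` fish were genotyped in
    *any* historical collection (archived scales amplify poorly), or if
    it is monomorphic across all collections pooled.
    """
    historical = collections.by_role("sink-historical")
    if not historical:
        raise ValueError("at least one historical collection is required")
    for l_idx, name in enumerate(collections.loci):
        if any(
            int((c.genotypes[:, l_idx] != MISSING).sum()) < min_typed for c in historical
        ):
            panel.remove(name, "low-coverage")
    for l_idx, name in enumerate(collections.loci):
        ref = alt = 0
        for c in collections:
            g = c.genotypes[:, l_idx]
            typed = g[g != MISSING]
            ref += int(typed.sum())
            alt += int(2 * typed.size - typed.sum())
        if ref == 0 or alt == 0:
            panel.remove(name, "invariant")
    return panel


def _hwe_log_weights(n_ref: int, n_tot: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Returns the possible heterozygote counts and their log-probabilities:
    P(h | n_ref, n) = n! 2^h n_ref! n_alt! / (n_AA! h! n_aa! (2n)!).
    """
    n_alt = 2 * n_tot - n_ref
    h_max = min(n_ref, n_alt)
    hs = np.arange(h_max % 2, h_max + 1, 2)
    n_aa_ref = (n_ref - hs) // 2
    n_aa_alt = (n_alt - hs) // 2
    logw = (
        gammaln(n_tot + 1)
        - gammaln(n_aa_ref + 1)
        - gammaln(hs + 1)
        - gammaln(n_aa_alt + 1)
        + hs * np.log(2.0)
        + gammaln(n_ref + 1)
        + gammaln(n_alt + 1)
        - gammaln(2 * n_tot + 1)
    )
    return hs, logw


def hwe_exact_test(counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic locus.

    Conditions on the observed allele counts, enumerates every
    compatible heterozygote count, and sums the probabilities of all
    outcomes no more probable than the observed one (two-sided
    probability ordering).
    """
    n_aa1, n_het, n_aa2 = (int(c) for c in counts)
    if min(n_aa1, n_het, n_aa2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_tot = n_aa1 + n_het + n_aa2
    if n_tot == 0:
        raise ValueError("at least one genotype is required")
    n_ref = 2 * n_aa1 + n_het
    hs, logw = _hwe_log_weights(n_ref, n_tot)
    log_obs = float(logw[hs == n_het][0])
    # include ties up to floating-point jitter
    p = float(np.exp(logw[logw <= log_obs + 1e-9 * abs(log_obs) + 1e-12]).sum())
    return min(p, 1.0)


def sequential_bonferroni(p_values, alpha: float = 0.01) -> np.ndarray:
    """Holm's sequentially rejective multiple-test procedure.

    Sorts ascending, compares the i-th smallest p to ``alpha/(k-i+1)``,
    and stops rejecting at the first failure; flags are returned in the
    input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    k = p.size
    flags = np.zeros(k, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (k - rank):
            flags[idx] = True
        else:
            break
    return flags


def hwe_locus_screen(
    collections: CollectionSet, panel: LocusPanel, alpha: float = 0.01
) -> LocusPanel:
    """Remove loci out of HWE in a majority of collections.

    Exact tests per locus per collection; sequential-Bonferroni
    correction across loci within each collection; a locus is removed
    iff it remains significant in strictly more than half of the
    collections.
    """
    names = [l for l in panel.loci if panel.status[l] == "retained"]
    idx = [collections.loci.index(l) for l in names]
    n_coll = len(collections.collections)
    sig = np.zeros((n_coll, len(names)), dtype=bool)
    for ci, coll in enumerate(collections):
        counts = coll.genotype_counts()[idx]
        pvals = [
            hwe_exact_test(tuple(c)) if c.sum() > 0 else 1.0 for c in counts
        ]
        sig[ci] = sequential_bonferroni(pvals, alpha)
    majority = sig.sum(axis=0) > n_coll / 2
    for name, bad in zip(names, majority):
        if bad:
            panel.remove(name, "HWE")
    return panel


def _g_statistic(codes: np.ndarray, expected: np.ndarray, n_cells: int) -> np.ndarray:
    """Log-likelihood-ratio G over rows of flattened-table codes."""
    n_rows = codes.shape[0]
    offset = codes + n_cells * np.arange(n_rows)[:, None]
    counts = np.bincount(offset.ravel(), minlength=n_cells * n_rows).reshape(
        n_rows, n_cells
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / expected)
    return 2.0 * np.nansum(terms, axis=1)


def ld_pair_test(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation test of genotypic association between two loci.

    Computes the log-likelihood-ratio G statistic on the 3x3 genotype
    table and compares it with its distribution under random pairing of
    the two columns; individuals missing at either locus are dropped.
    Monomorphic columns make the statistic constant, so p = 1.
    """
    rng = rng or np.random.default_rng()
    a = np.asarray(geno_a)
    b = np.asarray(geno_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(np.intp), b[ok].astype(np.intp)
    if a.size < 2:
        raise ValueError("fewer than 2 individuals typed at both loci")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return 1.0
    n = a.size
    row = np.bincount(a, minlength=3)
    col = np.bincount(b, minlength=3)
    expected = np.outer(row, col).ravel() / n
    obs_g = _g_statistic((3 * a + b)[None, :], expected, 9)[0]
    perms = b[np.argsort(rng.random((n_perm, n)), axis=1)]
    perm_g = _g_statistic(3 * a[None, :] + perms, expected, 9)
    return float((1 + np.sum(perm_g >= obs_g - 1e-12)) / (n_perm + 1))


def prune_linked_loci(
    ld_pvalues: dict[tuple[str, str], np.ndarray],
    panel: LocusPanel,
    known_linked_pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> LocusPanel:
    """Drop one locus from each pair in linkage disequilibrium.

    A pair is "linked" when significant at ``alpha`` in strictly more
    than half of the collections, or when listed as known-linked.  Chains
    (a locus linked to several partners) are broken first by removing the
    locus with the most linked partners; simple pairs then lose the locus
    with the lower heterozygosity, ties broken by the larger historical
    missing-data fraction, then by name.
    """
    known = {tuple(sorted(p)) for p in (known_linked_pairs or [])}
    edges: set[tuple[str, str]] = set()
    for (la, lb), pvals in ld_pvalues.items():
        pvals = np.asarray(pvals, dtype=float)
        if (pvals < alpha).sum() > pvals.size / 2:
            edges.add(tuple(sorted((la, lb))))
    edges |= {p for p in known if p[0] in panel.status and p[1] in panel.status}

    def worse(la: str, lb: str) -> str:
        """The locus to discard from a tied-degree pair."""
        ha = panel.heterozygosity.get(la, np.nan)
        hb = panel.heterozygosity.get(lb, np.nan)
        if not np.isnan(ha) and not np.isnan(hb) and ha != hb:
            return la if ha < hb else lb
        ma = panel.historical_missing.get(la, 0.0)
        mb = panel.historical_missing.get(lb, 0.0)
        if ma != mb:
            return la if ma > mb else lb
        return max(la, lb)

    active = set(edges)
    while active:
        degree: dict[str, int] = {}
        for la, lb in active:
            degree[la] = degree.get(la, 0) + 1
            degree[lb] = degree.get(lb, 0) + 1
        max_deg = max(degree.values())
        if max_deg > 1:
            cands = sorted(l for l, d in degree.items() if d == max_deg)
            if len(cands) > 1:
                # tie: fall back to the pairwise rule among the candidates
                drop = cands[0]
                for other in cands[1:]:
                    drop = worse(drop, other)
            else:
                drop = cands[0]
        else:
            la, lb = sorted(active)[0]
            drop = worse(la, lb)
        panel.remove(drop, "linked")
        active = {e for e in active if drop not in e}
    return panel


def microsat_contamination_screen(
    observed: list[list[frozenset[int] | None]],
) -> tuple[np.ndarray, int]:
    """Flag individuals whose extract shows more than two alleles at any
    multi-allelic locus.

    A locus scored as ``None`` (or an empty set) is unscored; an
    individual with no scored loci cannot be screened and is returned
    unflagged, counted in the second return value.
    """
    flags = np.zeros(len(observed), dtype=bool)
    unscreened = 0
    for i, loci in enumerate(observed):
        scored = [s for s in loci if s]
        if not scored:
            unscreened += 1
            continue
        flags[i] = any(len(s) >= 3 for s in scored)
    return flags, unscreened


def replicate_concordance(
    original: np.ndarray, replicate: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Discordance between first-pass and re-run genotypes.

    Considers only genotypes scored in both passes.  Returns per-locus
    discordance, the overall discordance, and the implied per-pass error
    rate (half the discordance, attributing disagreements equally to the
    two passes).
    """
    original = np.asarray(original)
    replicate = np.asarray(replicate)
    if original.shape != replicate.shape:
        raise ValueError("replicate must cover the same individuals and loci")
    both = (original != MISSING) & (replicate != MISSING)
    if not both.any():
        raise ValueError("no doubly-scored genotypes to compare")
    disagree = both & (original != replicate)
    with np.errstate(invalid="ignore"):
        per_locus = np.where(
            both.sum(axis=0) > 0, disagree.sum(axis=0) / both.sum(axis=0), np.nan
        )
    overall = float(disagree.sum() / both.sum())
    return per_locus, overall, overall / 2.0
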