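"""Core in-memory containers shared by every analysis stage.

Genotypes are biallelic SNP calls stored as the count of the reference
allele per individual per locus: 0 (homozygous alternate), 1
(heterozygous), 2 (homozygous reference), with ``MISSING`` (-1) for a
failed call.  A :class:`Collection` is one sampling event (one site in
one era); a :class:`CollectionSet` is the whole study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Valid collection roles.
ROLES = ("source", "sink-historical", "sink-contemporary")


@dataclass
class Collection:
    """Genotypes and metadata for one sampled collection.

    Parameters
    ----------
    name
        Collection label, e.g. ``"WellsRiver-hist"``.
    genotypes
        ``(n_individuals, n_loci)`` int8 array of reference-allele
        counts in {0, 1, 2} with :data:`MISSING` for no-calls.
    ids
        Individual identifiers, one per row.
    role
        One of :data:`ROLES`.
    site
        Site label linking the historical and contemporary collections
        of the same stream; the source collection carries its own name.
    stray
        Boolean flag per individual: True if the fish carries a hatchery
        thermal otolith mark (known source-origin stray).
    """

    name: str
    genotypes: np.ndarray
    ids: list[str]
    role: str
    site: str
    stray: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D individuals x loci array")
        if len(self.ids) != self.genotypes.shape[0]:
            raise ValueError("ids length does not match genotype rows")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.stray is None:
            self.stray = np.zeros(self.n_individuals, dtype=bool)
        else:
            self.stray = np.asarray(self.stray, dtype=bool)
            if self.stray.shape != (self.n_individuals,):
                raise ValueError("stray flags must be one per individual")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0/1/2 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def subset_individuals(self, keep: np.ndarray) -> "Collection":
        """Return a copy restricted to the given individual index/boolean mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            genotypes=self.genotypes[keep],
            ids=[self.ids[i] for i in keep],
            stray=self.stray[keep],
        )

    def subset_loci(self, keep: np.ndarray) -> "Collection":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(self, genotypes=self.genotypes[:, keep])

    def genotype_counts(self) -> np.ndarray:
        """Per-locus (n_AA, n_Aa, n_aa) counts over non-missing calls, shape (L, 3).

        Index 0 counts homozygous-reference (two copies), 1 heterozygous,
        2 homozygous-alternate.
        """
        g = self.genotypes
        return np.stack(
            [(g == 2).sum(axis=0), (g == 1).sum(axis=0), (g == 0).sum(axis=0)],
            axis=1,
        )


@dataclass
class CollectionSet:
    """All collections of a study sharing one locus panel."""

    collections: list[Collection]
    loci: list[str]

    def __post_init__(self) -> None:
        for c in self.collections:
            if c.n_loci != len(self.loci):
                raise ValueError(
                    f"collection {c.name!r} has {c.n_loci} loci, panel has {len(self.loci)}"
                )
        names = [c.name for c in self.collections]
        if len(set(names)) != len(names):
            raise ValueError("collection names must be unique")

    def __iter__(self):
        return iter(self.collections)

    def __len__(self) -> int:
        return len(self.collections)

    def get(self, name: str) -> Collection:
        for c in self.collections:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def sites(self) -> list[str]:
        """Sink site labels, in first-appearance order."""
        seen: list[str] = []
        for c in self.collections:
            if c.role != "source" and c.site not in seen:
                seen.append(c.site)
        return seen

    def by_role(self, role: str) -> list[Collection]:
        return [c for c in self.collections if c.role == role]

    def subset_loci(self, keep: np.ndarray) -> "CollectionSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CollectionSet(
            [c.subset_loci(keep) for c in self.collections],
            [self.loci[i] for i in keep],
        )


@dataclass
class TruthRecord:
    """Ground truth attached to a synthetic study for recovery tests."""

    Q: np.ndarray                       # (L,) source frequencies
    q0: np.ndarray                      # (n_sinks, L) pre-introgression sink frequencies
    qn: np.ndarray                      # (n_sinks, L) post-introgression sink frequencies
    m_true: np.ndarray                  # (n_sinks,) per-generation introgression rates
    n_generations: int
    contaminated: dict[str, np.ndarray] = field(default_factory=dict)  # per collection
    stray: dict[str, np.ndarray] = field(default_factory=dict)         # per collection
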