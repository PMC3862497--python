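"""Synthetic hatchery-wild introgression studies.

Emulates the statistical structure of the real study design: one
hatchery source collection plus several wild sink streams, each sampled
in a historical era (before hatchery production, frequencies ``q0``) and
a contemporary era (``n`` generations later, frequencies propagated with
the deterministic source-sink forecast).  Historical collections carry
heavy two-fish DNA cross-contamination (archival scale extracts);
contemporary collections carry a small fraction of otolith-marked source
strays.  Every collection is drawn under Hardy-Weinberg and linkage
equilibrium, the assumptions of the downstream models.

All randomness flows from a single seed through spawned child streams,
so an identical configuration reproduces a bit-identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, Collection, CollectionSet, TruthRecord
from .sourcesink import sink_frequency_forecast

__all__ = [
    "SimulationConfig",
    "draw_base_frequencies",
    "sample_genotype_matrix",
    "inject_contamination",
    "inject_missingness_and_strays",
    "simulate_microsatellites",
    "generate_study",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the real study's conditions: 135 biallelic loci,
    four sink streams with per-generation introgression rates spanning
    the estimated range, six generations of introgression, historical
    samples of ~60 fish half of which are cross-contaminated, and
    contemporary samples of several hundred fish with a small stray
    fraction.
    """

    n_loci: int = 135
    n_sinks: int = 4
    m_true: tuple[float, ...] = (0.257, 0.066, 0.060, 0.011)
    n_generations: int = 6
    n_source: int = 200
    n_historical: int = 140   # initial archived-scale sample; ~half survives the contamination screens
    n_contemporary: int = 500
    freq_law: tuple[float, float] = (0.05, 0.95)   # Uniform bounds for base frequencies
    contamination_rate: float = 0.5                # historical collections only
    missing_rate: float = 0.05
    stray_rate: float = 0.01                       # contemporary collections only
    microsat_loci: int = 7
    microsat_alleles: int = 10
    drift_ne: int | None = None                    # optional Wright-Fisher layer, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_sinks < 1:
            raise ValueError("n_loci and n_sinks must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be non-negative")
        if len(self.m_true) != self.n_sinks:
            raise ValueError("m_true must give one rate per sink")
        for r in (*self.m_true, self.contamination_rate, self.missing_rate, self.stray_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and probabilities must lie in [0, 1]")
        lo, hi = self.freq_law
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_law bounds must lie strictly inside (0, 1)")


def draw_base_frequencies(n_loci: int, freq_law: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Draw per-locus base allele frequencies from Uniform(lo, hi).

    A degenerate law with ``lo == hi`` is a point mass.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be positive")
    lo, hi = freq_law
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("freq_law bounds must lie strictly inside (0, 1)")
    return rng.uniform(lo, hi, size=n_loci)


def sample_genotype_matrix(freqs: np.ndarray, n_ind: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an ``(n_ind, L)`` genotype matrix under HWE and linkage
    equilibrium: each call is Binomial(2, p_l) copies of the reference
    allele, independent across individuals and loci."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if n_ind < 1:
        raise ValueError("n_ind must be positive")
    return rng.binomial(2, freqs, size=(n_ind, freqs.size)).astype(np.int8)


def _mix_two_fish(focal: np.ndarray, donor: np.ndarray) -> np.ndarray:
    """Apparent genotype of a two-fish DNA mixture.

    Pooling four alleles: scored homozygous only when all four agree,
    heterozygous otherwise (AAAA -> AA, aaaa -> aa, any mix -> Aa).
    """
    total = focal + donor  # reference-allele count among the 4 pooled alleles
    return np.where(total == 4, 2, np.where(total == 0, 0, 1)).astype(np.int8)


def inject_contamination(
    matrix: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-contaminate a fraction of individuals with one same-collection donor.

    Each individual is independently selected with probability ``rate``;
    a selected fish is mixed with a single uniformly chosen *other*
    individual of the same matrix, at all loci (contamination is a
    property of the DNA extract, not of single loci).  Returns the
    apparent matrix and the boolean truth flags.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    matrix = np.asarray(matrix, dtype=np.int8)
    n = matrix.shape[0]
    flags = rng.random(n) < rate
    if flags.any() and n < 2:
        raise ValueError("cannot contaminate a collection of one (no donor available)")
    apparent = matrix.copy()
    for i in np.flatnonzero(flags):
        donor = rng.integers(0, n - 1)
        if donor >= i:
            donor += 1  # uniform over the other n-1 individuals
        apparent[i] = _mix_two_fish(matrix[i], matrix[donor])
    return apparent, flags


def inject_missingness_and_strays(
    matrix: np.ndarray,
    missing_rate: float,
    stray_rate: float,
    source_freqs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-genotype missingness and replace a fraction of
    individuals by pure source-origin fish (otolith-marked strays).

    Strays are fresh HWE draws from the source frequencies — hatchery
    fish that died in the stream, not hybrids.  Missingness is uniform
    and independent per call, emulating degraded-template dropout.
    """
    for r in (missing_rate, stray_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    matrix = np.asarray(matrix, dtype=np.int8).copy()
    n = matrix.shape[0]
    stray = rng.random(n) < stray_rate
    if stray.any():
        matrix[stray] = sample_genotype_matrix(source_freqs, int(stray.sum()), rng)
    if missing_rate > 0:
        matrix[rng.random(matrix.shape) < missing_rate] = MISSING
    return matrix, stray


def simulate_microsatellites(
    n_ind: int,
    allele_freqs: list[np.ndarray],
    contaminated: np.ndarray,
    donors: np.ndarray,
    rng: np.random.Generator,
) -> list[list[frozenset[int]]]:
    """Observed allele sets at multi-allelic loci, per individual per locus.

    Clean individuals show their own (<=2) alleles; a contaminated
    extract shows the union of its own and its donor's alleles (up to 4),
    which is what makes >2 observed alleles diagnostic of contamination.

    Parameters
    ----------
    allele_freqs
        One frequency vector per microsatellite locus (each summing to 1).
    contaminated, donors
        Truth flags and, for contaminated individuals, the donor row index
        (ignored elsewhere).
    """
    for f in allele_freqs:
        if abs(float(np.sum(f)) - 1.0) > 1e-8:
            raise ValueError("allele frequencies at each locus must sum to 1")
        if len(f) < 2:
            raise ValueError("microsatellite loci need >= 2 alleles")
    genotypes = [
        rng.choice(len(f), size=(n_ind, 2), p=np.asarray(f, dtype=float) / np.sum(f))
        for f in allele_freqs
    ]
    out: list[list[frozenset[int]]] = []
    for i in range(n_ind):
        row = []
        for g in genotypes:
            own = set(g[i])
            if contaminated[i]:
                own |= set(g[donors[i]])
            row.append(frozenset(own))
        out.append(row)
    return out


def _contaminate_with_donors(
    matrix: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Like :func:`inject_contamination` but also returns donor indices,
    so the SNP and microsatellite panels share the same mixing event."""
    n = matrix.shape[0]
    flags = rng.random(n) < rate
    if flags.any() and n < 2:
        raise ValueError("cannot contaminate a collection of one")
    donors = np.full(n, -1, dtype=int)
    apparent = np.asarray(matrix, dtype=np.int8).copy()
    for i in np.flatnonzero(flags):
        d = rng.integers(0, n - 1)
        if d >= i:
            d += 1
        donors[i] = d
        apparent[i] = _mix_two_fish(matrix[i], matrix[d])
    return apparent, flags, donors


@dataclass
class SyntheticStudy:
    """A generated study: collections, truth, and microsatellite panels."""

    collections: CollectionSet
    truth: TruthRecord
    microsats: dict[str, list[list[frozenset[int]]]] = field(default_factory=dict)
    config: SimulationConfig | None = None


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from one seed.

    One source collection at frequencies ``Q``; per sink, a historical
    collection at ``q0`` and a contemporary collection at the source-sink
    forecast ``qn``.  Historical collections are cross-contaminated at the
    configured rate and carry a microsatellite panel; contemporary
    collections carry missingness and otolith-marked strays.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(2 + 3 * config.n_sinks)]
    rng_freq, rng_source = rngs[0], rngs[1]
    sink_rngs = rngs[2:]

    Q = draw_base_frequencies(config.n_loci, config.freq_law, rng_freq)
    q0 = np.stack(
        [
            draw_base_frequencies(config.n_loci, config.freq_law, rng_freq)
            for _ in range(config.n_sinks)
        ]
    )
    m = np.asarray(config.m_true, dtype=float)
    if config.drift_ne is None:
        qn = sink_frequency_forecast(q0, Q, m[:, None], config.n_generations)
    else:
        qn = q0.copy()
        for _ in range(config.n_generations):
            qn = (1.0 - m[:, None]) * qn + m[:, None] * Q
            qn = rng_freq.binomial(2 * config.drift_ne, qn) / (2.0 * config.drift_ne)

    loci = [f"snp{j:03d}" for j in range(config.n_loci)]
    ms_freqs = [
        np.full(config.microsat_alleles, 1.0 / config.microsat_alleles)
        for _ in range(config.microsat_loci)
    ]

    collections: list[Collection] = []
    truth = TruthRecord(
        Q=Q, q0=q0, qn=qn, m_true=m, n_generations=config.n_generations
    )
    microsats: dict[str, list[list[frozenset[int]]]] = {}

    src = sample_genotype_matrix(Q, config.n_source, rng_source)
    src, _ = inject_missingness_and_strays(src, config.missing_rate, 0.0, Q, rng_source)
    name = "hatchery"
    collections.append(
        Collection(
            name=name,
            genotypes=src,
            ids=[f"{name}_{i:04d}" for i in range(config.n_source)],
            role="source",
            site=name,
        )
    )
    truth.contaminated[name] = np.zeros(config.n_source, dtype=bool)
    truth.stray[name] = np.zeros(config.n_source, dtype=bool)

    for s in range(config.n_sinks):
        site = f"sink{s + 1}"
        rng_h, rng_c, rng_ms = sink_rngs[3 * s : 3 * s + 3]

        hist = sample_genotype_matrix(q0[s], config.n_historical, rng_h)
        hist, con_flags, donors = _contaminate_with_donors(
            hist, config.contamination_rate, rng_h
        )
        hist, _ = inject_missingness_and_strays(
            hist, config.missing_rate, 0.0, Q, rng_h
        )
        hname = f"{site}-hist"
        collections.append(
            Collection(
                name=hname,
                genotypes=hist,
                ids=[f"{hname}_{i:04d}" for i in range(config.n_historical)],
                role="sink-historical",
                site=site,
            )
        )
        truth.contaminated[hname] = con_flags
        truth.stray[hname] = np.zeros(config.n_historical, dtype=bool)
        if config.microsat_loci > 0:
            microsats[hname] = simulate_microsatellites(
                config.n_historical, ms_freqs, con_flags, donors, rng_ms
            )

        cont = sample_genotype_matrix(qn[s], config.n_contemporary, rng_c)
        cont, stray_flags = inject_missingness_and_strays(
            cont, config.missing_rate, config.stray_rate, Q, rng_c
        )
        cname = f"{site}-cont"
        collections.append(
            Collection(
                name=cname,
                genotypes=cont,
                ids=[f"{cname}_{i:04d}" for i in range(config.n_contemporary)],
                role="sink-contemporary",
                site=site,
                stray=stray_flags,
            )
        )
        truth.contaminated[cname] = np.zeros(config.n_contemporary, dtype=bool)
        truth.stray[cname] = stray_flags

    return SyntheticStudy(
        collections=CollectionSet(collections, loci),
        truth=truth,
        microsats=microsats,
        config=config,
    )
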