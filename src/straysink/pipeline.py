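"""End-to-end orchestration of the introgression analysis.

Stage order: (optional) synthetic-study generation -> individual filters
(otolith strays, missing-data) -> microsatellite contamination screen ->
locus coverage / invariance filters -> Bayesian contamination screen and
exclusion -> HWE and LD locus screens -> population summaries ->
per-sink source-sink introgression estimation.  Every stage draws its
randomness from one configured seed, so a run is reproducible from its
config alone.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc
from .containers import MISSING, CollectionSet
from .contamination import classify_contaminated, run_contamination_mcmc
from .mcmc import McmcSpec
from .popgen import allele_frequencies, divergence_matrix, heterozygosities
from .simulate import SimulationConfig, SyntheticStudy, generate_study
from .sourcesink import (
    IntrogressionEstimate,
    SourceSinkData,
    run_introgression_mcmc,
    slope_diagnostic,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and run sizes for one pipeline execution.

    QC defaults follow the study protocol: 20% missing-data cutoff,
    55-fish locus coverage rule in historical collections, HWE screen at
    alpha 0.01, LD screen at alpha 0.05, contamination exclusion at
    posterior 0.75, and n = 6 generations of introgression.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_missing: float = 0.20
    min_typed: int = 55
    hwe_alpha: float = 0.01
    ld_alpha: float = 0.05
    ld_n_perm: int = 199
    run_ld_screen: bool = True
    contamination_threshold: float = 0.75
    contamination_iterations: int = 10_000
    contamination_burnin: int = 5_000
    introgression_iterations: int = 20_000
    introgression_burnin: int = 10_000
    n_generations: int = 6
    seed: int = 0
    out_dir: str | None = None


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the truth when simulated."""

    collections: CollectionSet                 # post-QC
    qc_report: qc.QcReport
    locus_panel: qc.LocusPanel
    contamination: dict[str, pd.DataFrame]
    divergence: pd.DataFrame
    introgression: dict[str, IntrogressionEstimate]
    slopes: dict[str, float]
    truth: object | None = None

    def introgression_frame(self) -> pd.DataFrame:
        rows = [
            {
                "location": site,
                "m": est.posterior_mean,
                "q2.5": est.ci_lower,
                "q97.5": est.ci_upper,
                "slope": self.slopes[site],
                "rhat": est.rhat,
                "status": est.status,
            }
            for site, est in self.introgression.items()
        ]
        return pd.DataFrame(rows)


def _collection_seed(base: int, tag: str) -> int:
    """Stable per-stage sub-seed below 2**31 (crc32 keeps it
    reproducible across processes, unlike the builtin str hash)."""
    mix = np.random.SeedSequence([base, zlib.crc32(tag.encode())])
    return int(mix.generate_state(1, np.uint32)[0] % (2**31))


def run_pipeline(
    config: PipelineConfig, study: SyntheticStudy | None = None
) -> PipelineResult:
    """Run the full analysis on a synthetic (or supplied) study.

    When ``study`` is None one is generated from ``config.simulation``
    (with the pipeline seed folded in).  Writes report tables under
    ``config.out_dir`` when set.
    """
    if study is None:
        sim_cfg = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
        study = generate_study(sim_cfg)
    collections = study.collections

    report = qc.QcReport()
    panel = qc.LocusPanel(list(collections.loci))

    # -- individual filters: strays and missing data --
    kept = []
    for coll in collections:
        report.start(coll.name, coll.n_individuals)
        keep_idx, removed = qc.filter_individuals(coll, config.max_missing)
        report.record(coll.name, "stray", len(removed["stray"]))
        report.record(coll.name, "missing", len(removed["missing"]))
        sub = coll.subset_individuals(keep_idx)
        # -- microsatellite screen (collections with a microsat panel) --
        if coll.name in study.microsats:
            obs = [study.microsats[coll.name][i] for i in keep_idx]
            flags, _ = qc.microsat_contamination_screen(obs)
            report.record(coll.name, "microsat", int(flags.sum()))
            sub = sub.subset_individuals(~flags)
        kept.append(sub)
    collections = CollectionSet(kept, list(collections.loci))

    # -- locus coverage and invariance --
    panel = qc.filter_loci(collections, panel, config.min_typed)

    # -- Bayesian contamination screen on the retained panel --
    contamination: dict[str, pd.DataFrame] = {}
    mask = panel.retained_mask()
    kept = []
    for coll in collections:
        spec = McmcSpec(
            n_iterations=config.contamination_iterations,
            n_burnin=config.contamination_burnin,
            seed=_collection_seed(config.seed, f"contamination/{coll.name}"),
        )
        res = run_contamination_mcmc(coll.genotypes[:, mask], spec)
        excluded = classify_contaminated(res, config.contamination_threshold)
        contamination[coll.name] = pd.DataFrame(
            {
                "id": coll.ids,
                "posterior": res.posterior,
                "bayes_factor": res.bayes_factor,
                "excluded": np.isin(np.arange(coll.n_individuals), excluded),
            }
        )
        report.record(coll.name, "hwe_model", len(excluded))
        keep = np.setdiff1d(np.arange(coll.n_individuals), excluded)
        kept.append(coll.subset_individuals(keep))
    collections = CollectionSet(kept, list(collections.loci))

    # -- locus screens on the cleaned collections --
    panel = qc.hwe_locus_screen(collections, panel, config.hwe_alpha)
    het = heterozygosity_by_locus(collections)
    hist_missing = historical_missing_by_locus(collections)
    panel.heterozygosity.update(het)
    panel.historical_missing.update(hist_missing)
    if config.run_ld_screen:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7_777_777])
        )
        ld_pvals = ld_screen_pvalues(
            collections, panel.retained, config.ld_n_perm, rng
        )
        panel = qc.prune_linked_loci(ld_pvals, panel, alpha=config.ld_alpha)

    final = collections.subset_loci(
        np.array([panel.status[l] == "retained" for l in collections.loci])
    )

    # -- population summaries --
    divergence = divergence_matrix(final)

    # -- per-sink source-sink estimation --
    source = final.by_role("source")[0]
    introgression: dict[str, IntrogressionEstimate] = {}
    slopes: dict[str, float] = {}
    for site in final.sites:
        hist = next(
            c for c in final.by_role("sink-historical") if c.site == site
        )
        cont = next(
            c for c in final.by_role("sink-contemporary") if c.site == site
        )
        data = SourceSinkData(
            source.genotype_counts(),
            hist.genotype_counts(),
            cont.genotype_counts(),
            config.n_generations,
            loci=list(final.loci),
        )
        spec = McmcSpec(
            n_iterations=config.introgression_iterations,
            n_burnin=config.introgression_burnin,
            seed=_collection_seed(config.seed, f"introgression/{site}"),
        )
        introgression[site] = run_introgression_mcmc(data, spec)
        slopes[site] = slope_diagnostic(
            allele_frequencies(source)["frequency"].to_numpy(),
            allele_frequencies(hist)["frequency"].to_numpy(),
            allele_frequencies(cont)["frequency"].to_numpy(),
        )

    result = PipelineResult(
        collections=final,
        qc_report=report,
        locus_panel=panel,
        contamination=contamination,
        divergence=divergence,
        introgression=introgression,
        slopes=slopes,
        truth=study.truth,
    )
    if config.out_dir:
        _write_reports(result, config)
    return result


def heterozygosity_by_locus(collections: CollectionSet) -> dict[str, float]:
    """Mean expected heterozygosity per locus across collections (used by
    the linked-locus pruning rule)."""
    hes = np.nanmean(
        np.stack([heterozygosities(c)["He"].to_numpy() for c in collections]), axis=0
    )
    return dict(zip(collections.loci, hes))


def historical_missing_by_locus(collections: CollectionSet) -> dict[str, float]:
    """Missing-genotype fraction per locus over historical collections."""
    hist = collections.by_role("sink-historical")
    if not hist:
        return {l: 0.0 for l in collections.loci}
    miss = np.concatenate([c.genotypes == MISSING for c in hist], axis=0).mean(axis=0)
    return dict(zip(collections.loci, miss))


def ld_screen_pvalues(
    collections: CollectionSet,
    loci: list[str],
    n_perm: int,
    rng: np.random.Generator,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-collection LD permutation p-values for every retained locus pair."""
    idx = {l: collections.loci.index(l) for l in loci}
    out: dict[tuple[str, str], np.ndarray] = {}
    for la, lb in itertools.combinations(loci, 2):
        out[(la, lb)] = np.array(
            [
                qc.ld_pair_test(
                    c.genotypes[:, idx[la]], c.genotypes[:, idx[lb]], n_perm, rng
                )
                for c in collections
            ]
        )
    return out


def _write_reports(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    result.locus_panel.to_frame().to_csv(out / "locus_panel.tsv", sep="\t", index=False)
    result.divergence.to_csv(out / "divergence.tsv", sep="\t")
    result.introgression_frame().to_csv(out / "introgression.tsv", sep="\t", index=False)
    for name, frame in result.contamination.items():
        frame.to_csv(out / f"contamination_{name}.tsv", sep="\t", index=False)
    diag = {
        "seed": config.seed,
        "n_generations": config.n_generations,
        "introgression": {
            site: {"rhat": est.rhat, "status": est.status}
            for site, est in result.introgression.items()
        },
    }
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
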