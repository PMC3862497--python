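"""Seeded simulation experiments: parameter recovery and classifier
operating characteristics.

These drive the calibration analyses: genotype samples are drawn exactly
under the model (HWE at the source, historical and forecast contemporary
frequencies), fitted, and compared with the generating truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contamination import run_contamination_mcmc
from .mcmc import McmcSpec
from .simulate import draw_base_frequencies, inject_contamination, sample_genotype_matrix
from .sourcesink import SourceSinkData, run_introgression_mcmc, sink_frequency_forecast

__all__ = ["simulate_sink_counts", "recovery_replicates", "classifier_replicates"]


def _counts(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes)
    return np.stack([(g == 2).sum(0), (g == 1).sum(0), (g == 0).sum(0)], axis=1)


def simulate_sink_counts(
    m_true: float,
    rng: np.random.Generator,
    n_loci: int = 135,
    n_historical: int = 60,
    n_contemporary: int = 500,
    n_source: int = 200,
    n_generations: int = 6,
    freq_law: tuple[float, float] = (0.05, 0.95),
) -> SourceSinkData:
    """One sink's genotype counts drawn under the source-sink model."""
    q0 = draw_base_frequencies(n_loci, freq_law, rng)
    Q = draw_base_frequencies(n_loci, freq_law, rng)
    qn = sink_frequency_forecast(q0, Q, m_true, n_generations)
    return SourceSinkData(
        _counts(sample_genotype_matrix(Q, n_source, rng)),
        _counts(sample_genotype_matrix(q0, n_historical, rng)),
        _counts(sample_genotype_matrix(qn, n_contemporary, rng)),
        n_generations,
    )


def recovery_replicates(
    m_true: float,
    n_replicates: int,
    seed: int,
    n_iterations: int = 20_000,
    n_burnin: int = 10_000,
    **design,
) -> pd.DataFrame:
    """Repeatedly simulate a sink and re-estimate its introgression rate.

    Returns one row per replicate: posterior mean, 95% credible bounds,
    whether the interval covers the generating truth, and R-hat.
    """
    root = np.random.SeedSequence([seed, 424243])
    rows = []
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        data = simulate_sink_counts(m_true, rng, **design)
        spec = McmcSpec(
            n_iterations,
            n_burnin,
            seed=int(child.generate_state(1, np.uint32)[0] % 2**31),
        )
        est = run_introgression_mcmc(data, spec)
        rows.append(
            {
                "replicate": rep,
                "m_true": m_true,
                "posterior_mean": est.posterior_mean,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "covered": est.ci_lower <= m_true <= est.ci_upper,
                "rhat": est.rhat,
                "status": est.status,
            }
        )
    return pd.DataFrame(rows)


def classifier_replicates(
    contamination_rate: float,
    n_replicates: int,
    seed: int,
    n_individuals: int = 100,
    n_loci: int = 100,
    freq_law: tuple[float, float] = (0.2, 0.8),
    n_iterations: int = 10_000,
    n_burnin: int = 5_000,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Sensitivity and false-positive rate of the contamination classifier
    on synthetic collections with known contamination labels."""
    root = np.random.SeedSequence([seed, 515152])
    rows = []
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        p = draw_base_frequencies(n_loci, freq_law, rng)
        clean = sample_genotype_matrix(p, n_individuals, rng)
        apparent, flags = inject_contamination(clean, contamination_rate, rng)
        spec = McmcSpec(
            n_iterations,
            n_burnin,
            seed=int(child.generate_state(1, np.uint32)[0] % 2**31),
        )
        res = run_contamination_mcmc(apparent, spec)
        called = res.posterior > threshold
        rows.append(
            {
                "replicate": rep,
                "rate": contamination_rate,
                "n_contaminated": int(flags.sum()),
                "sensitivity": float(called[flags].mean()) if flags.any() else np.nan,
                "false_positive_rate": float(called[~flags].mean()),
                "rhat": res.rhat,
            }
        )
    return pd.DataFrame(rows)
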