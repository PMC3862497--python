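r"""Bayesian detection of two-fish DNA cross-contamination.

Archived fish scales carry surface DNA from other fish, so an extract
may be a mixture of exactly two individuals from the same collection.
Pooling four alleles and scoring a diploid call, the *apparent* genotype
is homozygous only when all four alleles agree; under Hardy-Weinberg at
frequency :math:`p` the apparent-genotype probabilities are therefore

==============  ==================  ============================
apparent call   single fish         two-fish mixture
==============  ==================  ============================
AA              :math:`p^2`         :math:`p^4`
Aa              :math:`2p(1-p)`     :math:`1 - p^4 - (1-p)^4`
aa              :math:`(1-p)^2`     :math:`(1-p)^4`
==============  ==================  ============================

Each individual carries a Bernoulli(1/2)-prior indicator :math:`z`
selecting between the two models at *all* loci jointly (contamination is
a property of the extract).  A Gibbs sampler alternates the exact full
conditionals of :math:`z` and of the allele frequencies — the latter via
latent-allele-count augmentation, which keeps the Beta(1/2, 1/2)
(Rannala-Mountain) frequency prior conjugate.  With equal prior weight,
the posterior mean of :math:`z` is the posterior probability of
contamination, and posterior > 0.75 corresponds to a Bayes factor > 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING
from .mcmc import McmcSpec, split_rhat

__all__ = [
    "ContaminationResult",
    "genotype_probs",
    "individual_loglik",
    "run_contamination_mcmc",
    "posterior_to_bayes_factor",
    "classify_contaminated",
]


def genotype_probs(p: float, model: str) -> np.ndarray:
    """Apparent-genotype probabilities (P(AA), P(Aa), P(aa)) at frequency ``p``.

    ``model`` is ``"uncontaminated"`` (single fish, ordinary HWE) or
    ``"contaminated"`` (two-fish mixture: HWE over four independent
    alleles collapsed to a diploid call).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    if model == "uncontaminated":
        return np.array([p * p, 2.0 * p * q, q * q])
    if model == "contaminated":
        return np.array([p**4, 1.0 - p**4 - q**4, q**4])
    raise ValueError(f"unknown model {model!r}")


def _log_prob_table(p: np.ndarray, contaminated: bool) -> np.ndarray:
    """(3, L) log apparent-genotype probabilities, rows indexed by the
    reference-allele count code (0 = aa, 1 = Aa, 2 = AA)."""
    q = 1.0 - p
    k = 4 if contaminated else 2
    with np.errstate(divide="ignore"):
        if contaminated:
            het = np.log(1.0 - p**4 - q**4)
        else:
            het = np.log(2.0 * p * q)
        return np.stack([k * np.log(q), het, k * np.log(p)])


def individual_loglik(genotypes: np.ndarray, freqs: np.ndarray, model: str) -> float:
    """Log-likelihood of one individual's calls under one model, summing
    over non-missing loci ("contaminated at one locus" means
    contaminated at all).  Returns -inf when an observed call has
    probability zero under the model; 0 when all loci are missing.
    """
    g = np.asarray(genotypes)
    p = np.asarray(freqs, dtype=float)
    if g.shape != p.shape:
        raise ValueError("genotypes and freqs must be aligned")
    ok = g != MISSING
    if not ok.any():
        return 0.0
    table = _log_prob_table(p, contaminated=(model == "contaminated"))
    if model not in ("contaminated", "uncontaminated"):
        raise ValueError(f"unknown model {model!r}")
    return float(table[g[ok].astype(np.intp), np.flatnonzero(ok)].sum())


@dataclass
class ContaminationResult:
    """Posterior contamination summary for one collection."""

    posterior: np.ndarray            # per-individual posterior mean of z
    bayes_factor: np.ndarray
    chain_posteriors: np.ndarray     # (n_chains, n_individuals)
    rhat: float                      # worst monitored split-chain R-hat
    status: str                      # "ok" | "non-convergence" | "uninformative"
    diagnostics: dict = field(default_factory=dict)


def run_contamination_mcmc(
    genotypes: np.ndarray, spec: McmcSpec
) -> ContaminationResult:
    """Gibbs sampler for per-individual contamination indicators.

    Alternates (a) each individual's indicator from its exact full
    conditional — Bernoulli with success probability
    ``L_con / (L_con + L_unc)`` under the equal-weight prior — and (b)
    conjugate Beta updates of each locus frequency via latent allele
    counts: a clean individual contributes its two alleles; a
    contaminated apparent homozygote contributes four copies of that
    allele; a contaminated apparent heterozygote contributes a latent
    reference-allele count c in {1, 2, 3} drawn proportional to
    ``C(4,c) p^c (1-p)^(4-c)``.

    One chain starts with every individual contaminated, the other with
    every individual clean.  Convergence is assessed by split-chain
    R-hat on each locus frequency and on the collection-mean indicator.
    """
    g = np.asarray(genotypes)
    n, L = g.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    ok = g != MISSING
    gi = np.where(ok, g, 0).astype(np.intp)

    # observed-monomorphic panel carries no information: prior returned
    poly = np.array(
        [np.unique(g[ok[:, l], l]).size > 1 for l in range(L)]
    )
    if not poly.any():
        post = np.full(n, 0.5)
        return ContaminationResult(
            posterior=post,
            bayes_factor=posterior_to_bayes_factor(post),
            chain_posteriors=np.full((spec.n_chains, n), 0.5),
            rhat=1.0,
            status="uninformative",
        )

    n_keep = spec.n_iterations - spec.n_burnin
    chain_post = np.empty((spec.n_chains, n))
    meanz_trace = np.empty((spec.n_chains, n_keep))
    p_trace = np.empty((spec.n_chains, n_keep, L))
    cols = np.arange(L)

    root = np.random.SeedSequence(spec.seed)
    for ci, child in enumerate(root.spawn(spec.n_chains)):
        rng = np.random.default_rng(child)
        z = np.full(n, ci % 2 == 0)  # all contaminated vs all clean
        # frequency init from pooled observed allele counts
        ref = (gi * ok).sum(axis=0).astype(float)
        tot = 2.0 * ok.sum(axis=0)
        p = np.clip((ref + 0.5) / (tot + 1.0), 1e-9, 1 - 1e-9)
        z_sum = np.zeros(n)

        for it in range(spec.n_iterations):
            # --- z | p: exact full conditional ---
            lpu = _log_prob_table(p, contaminated=False)
            lpc = _log_prob_table(p, contaminated=True)
            diff = np.where(ok, (lpc - lpu)[gi, cols], 0.0).sum(axis=1)
            prob_con = 1.0 / (1.0 + np.exp(-np.clip(diff, -700, 700)))
            z = rng.random(n) < prob_con

            # --- p | z: conjugate Beta via latent allele counts ---
            clean = ok & ~z[:, None]
            con = ok & z[:, None]
            ref_cnt = (gi * clean).sum(axis=0).astype(float)
            tot_cnt = 2.0 * clean.sum(axis=0)
            hom_ref = con & (gi == 2)
            hom_alt = con & (gi == 0)
            het = con & (gi == 1)
            ref_cnt += 4.0 * hom_ref.sum(axis=0)
            tot_cnt += 4.0 * (hom_ref.sum(axis=0) + hom_alt.sum(axis=0) + het.sum(axis=0))
            if het.any():
                q = 1.0 - p
                w1 = 4.0 * p * q**3
                w2 = 6.0 * p**2 * q**2
                w3 = 4.0 * p**3 * q
                norm = w1 + w2 + w3
                c1 = (w1 / norm)[None, :]
                c2 = ((w1 + w2) / norm)[None, :]
                u = rng.random((n, L))
                c = 1 + (u > c1) + (u > c2)
                ref_cnt += (c * het).sum(axis=0)
            p = rng.beta(0.5 + ref_cnt, 0.5 + tot_cnt - ref_cnt)
            p = np.clip(p, 1e-12, 1 - 1e-12)

            if it >= spec.n_burnin:
                z_sum += z
                meanz_trace[ci, it - spec.n_burnin] = z.mean()
                p_trace[ci, it - spec.n_burnin] = p

        chain_post[ci] = z_sum / n_keep

    posterior = chain_post.mean(axis=0)
    rhats = [split_rhat(meanz_trace)]
    rhats += [split_rhat(p_trace[:, :, l]) for l in np.flatnonzero(poly)]
    rhat = float(np.max(rhats))
    max_chain_gap = float(np.abs(chain_post[0] - chain_post[-1]).max())
    status = "ok" if rhat <= spec.convergence_threshold else "non-convergence"
    return ContaminationResult(
        posterior=posterior,
        bayes_factor=posterior_to_bayes_factor(posterior),
        chain_posteriors=chain_post,
        rhat=rhat,
        status=status,
        diagnostics={
            "max_chain_gap": max_chain_gap,
            "n_iterations": spec.n_iterations,
            "n_burnin": spec.n_burnin,
            "seed": spec.seed,
        },
    )


def posterior_to_bayes_factor(posterior, prior: float = 0.5):
    """Bayes factor from a posterior model probability:
    ``BF = [post/(1-post)] / [prior/(1-prior)]``; a posterior of exactly
    1 maps to +inf."""
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie in (0, 1)")
    post = np.asarray(posterior, dtype=float)
    if np.any(post < 0) or np.any(post > 1):
        raise ValueError("posterior must lie in [0, 1]")
    prior_odds = prior / (1.0 - prior)
    with np.errstate(divide="ignore"):
        out = np.where(post < 1.0, post / (1.0 - post), np.inf) / prior_odds
    return out if out.ndim else float(out)


def classify_contaminated(
    result: ContaminationResult, threshold: float = 0.75
) -> np.ndarray:
    """Indices of individuals whose posterior contamination probability
    strictly exceeds the threshold (the posterior-0.75 / Bayes-factor-3
    exclusion rule)."""
    return np.flatnonzero(result.posterior > threshold)
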