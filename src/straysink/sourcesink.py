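r"""Source-sink model of genetic introgression.

A wild "sink" population receives, each generation, a fraction
:math:`m` of its gene pool from a "source" (hatchery) population whose
allele frequencies :math:`Q_l` are held fixed.  The sink frequency at
locus :math:`l` then follows the recursion

.. math:: q_{t+1} = (1 - m)\, q_t + m\, Q_l,

whose closed form after :math:`n` generations is

.. math:: q_n = (1-m)^n q_0 + \bigl[1 - (1-m)^n\bigr] Q_l .

Consequently :math:`Q_l - q_n = (1-m)^n (Q_l - q_0)` at every locus:
plotting the contemporary deviation from the source against the
historical deviation gives a line through the origin with slope
:math:`(1-m)^n` — slope 1 without introgression, slope < 1 with it.

Estimation is Bayesian: genotype counts from the source, historical and
contemporary collections are multinomial under Hardy-Weinberg at
:math:`Q_l`, :math:`q_{0,l}` and :math:`q_n(q_{0,l}, Q_l, m)`
respectively; :math:`q_n` is never a free parameter.  Priors are
Beta(1/2, 1/2) on each frequency (the equal-weight Dirichlet of the
Rannala-Mountain assignment framework) and a Normal(0, 1000) prior on
:math:`m` truncated to [0, 1] — effectively flat.  Sampling is
Metropolis-within-Gibbs with reflected random-walk proposals, two
chains, dispersed :math:`m` starts, and a split-chain R-hat diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .mcmc import McmcSpec, reflect, split_rhat

__all__ = [
    "SourceSinkData",
    "IntrogressionEstimate",
    "sink_frequency_forecast",
    "cumulative_introgression",
    "hwe_multinomial_loglik",
    "source_sink_loglik",
    "run_introgression_mcmc",
    "slope_diagnostic",
]

_M_PRIOR_VAR = 1000.0  # variance of the (truncated) normal prior on m


def sink_frequency_forecast(q0, Q, m, n: int):
    """Closed-form sink allele frequency after ``n`` generations.

    ``q_n = (1-m)^n q0 + [1-(1-m)^n] Q``; equal to ``n`` applications of
    the one-generation recursion ``q <- (1-m) q + m Q``.  Accepts scalars
    or aligned arrays.
    """
    q0 = np.asarray(q0, dtype=float)
    Q = np.asarray(Q, dtype=float)
    m = np.asarray(m, dtype=float)
    if n < 0:
        raise ValueError("n must be non-negative")
    for name, v in (("q0", q0), ("Q", Q), ("m", m)):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    decay = (1.0 - m) ** n
    out = decay * q0 + (1.0 - decay) * Q
    return out if out.ndim else float(out)


def cumulative_introgression(m, n: int):
    """Total source-derived fraction of the sink gene pool after ``n``
    generations: ``1 - (1-m)^n``."""
    m = np.asarray(m, dtype=float)
    if n < 0:
        raise ValueError("n must be non-negative")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("m must lie in [0, 1]")
    out = 1.0 - (1.0 - m) ** n
    return out if out.ndim else float(out)


@dataclass
class SourceSinkData:
    """Per-locus genotype counts for one sink's three collections.

    Each count array has shape ``(L, 3)`` ordered (hom-ref, het, hom-alt),
    as produced by :meth:`straysink.containers.Collection.genotype_counts`.
    """

    source_counts: np.ndarray
    historical_counts: np.ndarray
    contemporary_counts: np.ndarray
    n_generations: int = 6
    loci: list[str] | None = None

    def __post_init__(self) -> None:
        self.source_counts = np.asarray(self.source_counts, dtype=float)
        self.historical_counts = np.asarray(self.historical_counts, dtype=float)
        self.contemporary_counts = np.asarray(self.contemporary_counts, dtype=float)
        shapes = {
            a.shape
            for a in (self.source_counts, self.historical_counts, self.contemporary_counts)
        }
        if len(shapes) != 1 or self.source_counts.ndim != 2 or self.source_counts.shape[1] != 3:
            raise ValueError("count arrays must share one (L, 3) shape")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")

    @property
    def n_loci(self) -> int:
        return self.source_counts.shape[0]


def hwe_multinomial_loglik(
    counts: np.ndarray, p: np.ndarray, include_coefficient: bool = True
) -> np.ndarray:
    """Per-locus multinomial log-likelihood of (hom-ref, het, hom-alt)
    counts under Hardy-Weinberg proportions at frequency ``p``.

    A genotype class observed with positive count but probability zero
    yields -inf for that locus.
    """
    counts = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.stack(
            [2.0 * np.log(p), np.log(2.0 * p * (1.0 - p)), 2.0 * np.log1p(-p)],
            axis=-1,
        )
        terms = np.where(counts > 0, counts * logs, 0.0)
    ll = terms.sum(axis=-1)
    if include_coefficient:
        n = counts.sum(axis=-1)
        ll = ll + gammaln(n + 1.0) - gammaln(counts + 1.0).sum(axis=-1)
    return ll


def source_sink_loglik(data: SourceSinkData, q0: np.ndarray, Q: np.ndarray, m: float) -> float:
    """Joint log-likelihood of the three collections' genotype counts.

    The contemporary frequency is the deterministic forecast
    ``q_n(q0, Q, m, n)`` — not a free parameter.
    """
    q0 = np.asarray(q0, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if q0.shape != (data.n_loci,) or Q.shape != (data.n_loci,):
        raise ValueError("q0 and Q must match the locus panel")
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    qn = sink_frequency_forecast(q0, Q, m, data.n_generations)
    return float(
        hwe_multinomial_loglik(data.source_counts, Q).sum()
        + hwe_multinomial_loglik(data.historical_counts, q0).sum()
        + hwe_multinomial_loglik(data.contemporary_counts, qn).sum()
    )


@dataclass
class IntrogressionEstimate:
    """Posterior summary of the per-generation introgression rate."""

    posterior_mean: float
    ci_lower: float
    ci_upper: float
    draws: np.ndarray                       # pooled post-burn-in m draws
    chain_draws: np.ndarray                 # (n_chains, n_draws)
    rhat: float
    status: str                             # "ok" | "non-convergence" | "weak-identification"
    n_generations: int
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.status != "non-convergence"


def _freq_init(counts: np.ndarray) -> np.ndarray:
    """Posterior-mean-style frequency initialisation from genotype counts."""
    n_ref = 2.0 * counts[:, 0] + counts[:, 1]
    n_tot = 2.0 * counts.sum(axis=1)
    return (n_ref + 0.5) / (n_tot + 1.0)


def _beta_half_logprior(p: np.ndarray) -> np.ndarray:
    # Beta(1/2, 1/2) up to its normalising constant
    return -0.5 * np.log(p) - 0.5 * np.log1p(-p)


def run_introgression_mcmc(
    data: SourceSinkData,
    spec: McmcSpec,
    n_generations: int | None = None,
    m_inits: tuple[float, ...] = (0.01, 0.5),
    m_prior: str = "flat-normal",
) -> IntrogressionEstimate:
    """Estimate the per-generation introgression rate ``m`` for one sink.

    Metropolis-within-Gibbs: per-locus reflected random-walk updates of
    the historical (``q0``) and source (``Q``) frequencies, then a scalar
    reflected random-walk update of ``m``.  Proposal scales adapt toward
    ~30-40% acceptance during burn-in and are frozen afterwards.  Chains
    start from dispersed ``m`` values.

    ``m_prior`` selects between the default Normal(0, 1000) prior on
    ``m`` truncated to [0, 1] (effectively uniform) and a
    ``"logit-normal"`` variant placing Normal(0, 1000) on logit(m).
    """
    if m_prior not in ("flat-normal", "logit-normal"):
        raise ValueError(f"unknown m_prior {m_prior!r}")

    def m_logprior(m: float) -> float:
        if m_prior == "flat-normal":
            return -(m**2) / (2.0 * _M_PRIOR_VAR)
        if not 0.0 < m < 1.0:
            return -np.inf
        logit = np.log(m) - np.log1p(-m)
        return (
            -(logit**2) / (2.0 * _M_PRIOR_VAR) - np.log(m) - np.log1p(-m)
        )
    if n_generations is not None:
        data = SourceSinkData(
            data.source_counts,
            data.historical_counts,
            data.contemporary_counts,
            n_generations,
            data.loci,
        )
    n = data.n_generations
    L = data.n_loci
    eps = 1e-9
    n_keep = spec.n_iterations - spec.n_burnin
    chain_draws = np.empty((spec.n_chains, n_keep))
    accs: dict[str, float] = {}

    # Under HWE the multinomial genotype likelihood reduces, up to a
    # constant, to a binomial in the allele counts:
    # ll(p) = n_ref log p + n_alt log(1-p).
    def allele_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ref = 2.0 * counts[:, 0] + counts[:, 1]
        return ref, 2.0 * counts.sum(axis=1) - ref

    src_ref, src_alt = allele_counts(data.source_counts)
    hist_ref, hist_alt = allele_counts(data.historical_counts)
    cont_ref, cont_alt = allele_counts(data.contemporary_counts)

    def ll_src(p):
        return src_ref * np.log(p) + src_alt * np.log1p(-p)

    def ll_hist(p):
        return hist_ref * np.log(p) + hist_alt * np.log1p(-p)

    def ll_cont(p):
        return cont_ref * np.log(p) + cont_alt * np.log1p(-p)

    root = np.random.SeedSequence(spec.seed)
    for ci, child in enumerate(root.spawn(spec.n_chains)):
        rng = np.random.default_rng(child)
        q0 = np.clip(_freq_init(data.historical_counts), eps, 1 - eps)
        Q = np.clip(_freq_init(data.source_counts), eps, 1 - eps)
        m = float(m_inits[ci % len(m_inits)])

        s_q0 = np.full(L, 0.05)
        s_Q = np.full(L, 0.05)
        s_m = 0.05

        decay = (1.0 - m) ** n
        qn = decay * q0 + (1 - decay) * Q
        cur_hist = ll_hist(q0) + _beta_half_logprior(q0)
        cur_src = ll_src(Q) + _beta_half_logprior(Q)
        cur_cont = ll_cont(np.clip(qn, eps, 1 - eps))
        acc_counts = {"q0": 0.0, "Q": 0.0, "m": 0.0}

        for it in range(spec.n_iterations):
            adapting = it < spec.n_burnin

            # --- q0 update (independent across loci given m, Q) ---
            prop = reflect(q0 + rng.normal(0.0, s_q0, L), eps, 1 - eps)
            prop_hist = ll_hist(prop) + _beta_half_logprior(prop)
            qn_prop = np.clip(decay * prop + (1 - decay) * Q, eps, 1 - eps)
            prop_cont = ll_cont(qn_prop)
            take = np.log(rng.random(L)) < (prop_hist + prop_cont) - (cur_hist + cur_cont)
            q0 = np.where(take, prop, q0)
            cur_hist = np.where(take, prop_hist, cur_hist)
            cur_cont = np.where(take, prop_cont, cur_cont)
            qn = np.where(take, qn_prop, qn)
            acc_counts["q0"] += take.mean()
            if adapting:
                s_q0 = np.clip(
                    s_q0 * np.exp((take - 0.35) / np.sqrt(it + 10.0)), 1e-4, 0.5
                )

            # --- Q update ---
            prop = reflect(Q + rng.normal(0.0, s_Q, L), eps, 1 - eps)
            prop_src = ll_src(prop) + _beta_half_logprior(prop)
            qn_prop = np.clip(decay * q0 + (1 - decay) * prop, eps, 1 - eps)
            prop_cont = ll_cont(qn_prop)
            take = np.log(rng.random(L)) < (prop_src + prop_cont) - (cur_src + cur_cont)
            Q = np.where(take, prop, Q)
            cur_src = np.where(take, prop_src, cur_src)
            cur_cont = np.where(take, prop_cont, cur_cont)
            qn = np.where(take, qn_prop, qn)
            acc_counts["Q"] += take.mean()
            if adapting:
                s_Q = np.clip(
                    s_Q * np.exp((take - 0.35) / np.sqrt(it + 10.0)), 1e-4, 0.5
                )

            # --- m update (scalar; contemporary likelihood only) ---
            m_prop = reflect(m + rng.normal(0.0, s_m))
            d_prop = (1.0 - m_prop) ** n
            qn_prop = np.clip(d_prop * q0 + (1 - d_prop) * Q, eps, 1 - eps)
            prop_cont = ll_cont(qn_prop)
            log_r = (prop_cont.sum() - cur_cont.sum()) + m_logprior(m_prop) - m_logprior(m)
            took = np.log(rng.random()) < log_r
            if took:
                m = m_prop
                decay = d_prop
                qn = qn_prop
                cur_cont = prop_cont
            acc_counts["m"] += took
            if adapting:
                s_m = min(
                    max(s_m * np.exp(((1.0 if took else 0.0) - 0.35) / np.sqrt(it + 10.0)), 1e-4),
                    0.5,
                )

            if it >= spec.n_burnin:
                chain_draws[ci, it - spec.n_burnin] = m

        for k in acc_counts:
            accs[f"{k}_chain{ci}"] = acc_counts[k] / spec.n_iterations

    draws = chain_draws.reshape(-1)
    rhat = split_rhat(chain_draws)
    mean = float(draws.mean())
    lo, hi = np.quantile(draws, [0.025, 0.975])
    status = "ok"
    if rhat > spec.convergence_threshold:
        status = "non-convergence"
    elif hi - lo > 0.5:
        # posterior nearly as wide as the prior: the historical and source
        # frequencies barely differ, so m is only weakly identified
        status = "weak-identification"
    return IntrogressionEstimate(
        posterior_mean=mean,
        ci_lower=float(lo),
        ci_upper=float(hi),
        draws=draws,
        chain_draws=chain_draws,
        rhat=rhat,
        status=status,
        n_generations=n,
        acceptance=accs,
    )


def slope_diagnostic(Q_hat: np.ndarray, q0_hat: np.ndarray, qn_hat: np.ndarray) -> float:
    """Through-origin regression slope of (Q - qn) on (Q - q0) across loci.

    The model predicts slope ``(1-m)^n`` exactly on noiseless input:
    1.0 without introgression, < 1 with it.
    """
    Q_hat = np.asarray(Q_hat, dtype=float)
    q0_hat = np.asarray(q0_hat, dtype=float)
    qn_hat = np.asarray(qn_hat, dtype=float)
    if not Q_hat.shape == q0_hat.shape == qn_hat.shape:
        raise ValueError("frequency vectors must be aligned")
    x = Q_hat - q0_hat
    y = Q_hat - qn_hat
    if np.count_nonzero(x) < 2:
        raise ValueError("need at least 2 loci with Q != q0")
    return float(x.dot(y) / x.dot(x))
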