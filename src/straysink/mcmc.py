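"""Shared MCMC plumbing: run specifications and convergence diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class McmcSpec:
    """Length and seeding of an MCMC run.

    Defaults follow the study protocol: two chains of 100,000 iterations
    with the first 50,000 discarded as burn-in.  ``convergence_threshold``
    is the largest split-chain potential-scale-reduction value accepted
    as converged.
    """

    n_iterations: int = 100_000
    n_burnin: int = 50_000
    n_chains: int = 2
    seed: int = 0
    convergence_threshold: float = 1.05

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for diagnostics")


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Parameters
    ----------
    chains
        ``(n_chains, n_draws)`` array of post-burn-in draws of one scalar
        quantity.  Each chain is split in half, doubling the chain count,
        before the classic between/within variance ratio is formed.

    Returns
    -------
    float
        R-hat; 1.0 indicates perfect mixing.  Returns 1.0 for a quantity
        with zero variance everywhere (a constant is trivially converged).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    half = chains.shape[1] // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    w = split.var(axis=1, ddof=1).mean()
    b = n * split.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def reflect(x: np.ndarray | float, lo: float = 0.0, hi: float = 1.0):
    """Reflect proposals back into [lo, hi] (preserves detailed balance
    for a symmetric random walk)."""
    x = np.asarray(x, dtype=float)
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    out = lo + y
    return out if out.ndim else float(out)
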