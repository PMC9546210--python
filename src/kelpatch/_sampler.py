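"""Adaptive block random-walk Metropolis sampler.

Parameters are updated in blocks; each block carries its own proposal
scale (Robbins–Monro adapted toward a target acceptance rate) and, once
enough warmup history exists, an empirical proposal covariance
(Haario-style adaptive Metropolis).  Adaptation runs only during warmup,
so the post-warmup chain is a valid Metropolis chain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["run_chain"]

_TARGET_ACCEPT = 0.25
_COV_REFRESH = 100  # recompute proposal Cholesky every this many warmup iters


def run_chain(
    logpost,
    x0: np.ndarray,
    blocks: list[np.ndarray],
    *,
    n_warmup: int,
    n_draws: int,
    thin: int = 1,
    rng: np.random.Generator,
    init_chols: list | None = None,
) -> tuple[np.ndarray, float]:
    """Run one chain; returns (draws [n_draws, P], mean acceptance rate).

    ``init_chols`` optionally seeds per-block proposal Cholesky factors
    (e.g. from a Laplace approximation at the mode); adaptation then
    refines them.
    """
    x = np.asarray(x0, dtype=float).copy()
    P = x.size
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior is not finite at the initial point")

    nb = len(blocks)
    if init_chols is not None:
        chols = list(init_chols)
        log_scale = np.array(
            [
                np.log((2.38 if chols[i] is not None else 0.3) / np.sqrt(len(b)))
                for i, b in enumerate(blocks)
            ]
        )
    else:
        chols = [None] * nb
        log_scale = np.array([np.log(0.3 / np.sqrt(len(b))) for b in blocks])
    # Welford accumulators for per-block empirical covariance
    counts = np.zeros(nb, dtype=int)
    means = [np.zeros(len(b)) for b in blocks]
    m2s = [np.zeros((len(b), len(b))) for b in blocks]

    draws = np.empty((n_draws, P))
    n_total = n_warmup + n_draws * thin
    n_prop = 0
    n_acc = 0
    for it in range(n_total):
        warm = it < n_warmup
        for bi, idx in enumerate(blocks):
            d = idx.size
            step = rng.standard_normal(d)
            if chols[bi] is not None:
                step = chols[bi] @ step
            prop = x.copy()
            prop[idx] = x[idx] + np.exp(log_scale[bi]) * step
            lp_prop = logpost(prop)
            accept = np.log1p(-rng.random()) < lp_prop - lp
            if accept:
                x = prop
                lp = lp_prop
            n_prop += 1
            n_acc += accept
            if warm:
                # Robbins–Monro step-size adaptation
                gamma = (it + 1) ** -0.6
                log_scale[bi] += gamma * ((1.0 if accept else 0.0) - _TARGET_ACCEPT)
                # covariance accumulation
                counts[bi] += 1
                delta = x[idx] - means[bi]
                means[bi] += delta / counts[bi]
                m2s[bi] += np.outer(delta, x[idx] - means[bi])
                if counts[bi] > max(2 * d, 20) and counts[bi] % _COV_REFRESH == 0:
                    cov = m2s[bi] / (counts[bi] - 1)
                    cov[np.diag_indices(d)] += 1e-8 + 1e-6 * np.trace(cov) / d
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        chol = None
                    if chol is not None:
                        if chols[bi] is None:
                            # first switch to the empirical-covariance proposal:
                            # restart the scale near the Haario optimum
                            log_scale[bi] = np.log(2.38 / np.sqrt(d))
                        chols[bi] = chol
        if not warm:
            j = it - n_warmup
            if (j + 1) % thin == 0:
                draws[(j + 1) // thin - 1] = x
    return draws, n_acc / max(n_prop, 1)
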