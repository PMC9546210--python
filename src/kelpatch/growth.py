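"""Size-class growth transition matrix.

Annual growth follows a Brody/von Bertalanffy mean increment with Gaussian
noise: an individual of test diameter L grows on average by
``(L_inf - L) * (1 - exp(-k))`` cm in one year, with standard deviation
``increment_sd``.  Probability mass is integrated over the destination
1-cm bins, truncated so that no individual shrinks out of its current
class, and renormalised.  The largest class is a plus-group that absorbs
all further growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import InvalidBinsError, InvalidParamsError

__all__ = ["GrowthParams", "GrowthMatrix", "build_growth_matrix", "bin_midpoints"]


@dataclass(frozen=True)
class GrowthParams:
    """Von Bertalanffy growth parameters on the cm / year scale.

    asymptotic_size : asymptotic test diameter L_inf (cm), > 0
    growth_rate     : Brody coefficient k (1/yr), >= 0
    increment_sd    : SD of the annual growth increment (cm), > 0
    """

    asymptotic_size: float
    growth_rate: float
    increment_sd: float

    def validate(self) -> None:
        if not (self.asymptotic_size > 0):
            raise InvalidParamsError("asymptotic_size must be > 0")
        if not (self.growth_rate >= 0):
            raise InvalidParamsError("growth_rate must be >= 0")
        if not (self.increment_sd > 0):
            raise InvalidParamsError("increment_sd must be > 0")


@dataclass(frozen=True)
class GrowthMatrix:
    """Row-stochastic matrix of one-year size-class transitions.

    ``probs[j, k]`` is the probability that an individual in class j is in
    class k one year later, conditional on survival.  Entries with k < j
    are zero (no shrinkage).
    """

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise InvalidParamsError("growth matrix must be square")
        if np.any(p < 0):
            raise InvalidParamsError("growth matrix entries must be non-negative")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-9:
            raise InvalidParamsError("growth matrix rows must sum to 1")
        if np.any(np.tril(p, k=-1) != 0):
            raise InvalidParamsError("growth matrix must have zero mass below the diagonal")
        object.__setattr__(self, "probs", p)

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]


def _validate_bin_edges(bin_edges: np.ndarray) -> np.ndarray:
    e = np.asarray(bin_edges, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise InvalidBinsError("bin_edges must be a 1-d vector of length >= 2")
    if not np.all(np.diff(e) > 0):
        raise InvalidBinsError("bin_edges must be strictly increasing")
    return e


def bin_midpoints(bin_edges: np.ndarray) -> np.ndarray:
    """Midpoints of the size bins; the plus-group (upper edge inf) uses its
    lower edge plus half the mean width of the finite bins."""
    e = _validate_bin_edges(bin_edges)
    mids = 0.5 * (e[:-1] + e[1:])
    if np.isinf(e[-1]):
        widths = np.diff(e[:-1])
        half = 0.5 * (widths.mean() if widths.size else 1.0)
        mids[-1] = e[-2] + half
    return mids


def build_growth_matrix(params: GrowthParams, bin_edges: np.ndarray) -> GrowthMatrix:
    """Construct the one-year size-class transition matrix.

    Each source class is represented by its bin midpoint; the post-growth
    size is Gaussian around the von Bertalanffy mean, with mass below the
    source bin's lower edge truncated (no shrinkage) and the remainder
    renormalised over destination classes >= the source class.

    Degenerate case: ``growth_rate == 0`` means no growth process at all,
    so every individual stays in its class (identity matrix).
    """
    params.validate()
    e = _validate_bin_edges(bin_edges)
    S = e.size - 1
    if params.growth_rate == 0.0:
        return GrowthMatrix(np.eye(S))

    mids = bin_midpoints(e)
    frac = 1.0 - np.exp(-params.growth_rate)
    G = np.zeros((S, S))
    for j in range(S):
        mean_dest = mids[j] + max(0.0, (params.asymptotic_size - mids[j]) * frac)
        # CDF of the destination size at every edge from the source bin up
        z = (e[j:] - mean_dest) / params.increment_sd
        cdf = norm.cdf(z)
        cdf[-1] = 1.0 if np.isinf(e[-1]) else cdf[-1]
        mass = np.diff(cdf)
        total = 1.0 - cdf[0]  # mass not truncated below the source bin
        if total <= 0:  # numerically all mass below: stay put
            G[j, j] = 1.0
            continue
        G[j, j:] = mass / total
    # clean tiny negative round-off and renormalise exactly
    G[G < 0] = 0.0
    G /= G.sum(axis=1, keepdims=True)
    return GrowthMatrix(G)
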