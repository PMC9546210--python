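"""Segmented (piecewise-linear) regression with multiple change points.

Annual density series are short (~23 points), so breakpoint placement is
found by exhaustive search over all admissible between-observation
positions, with ordinary least squares within each segment.  Segments
are fitted as disconnected lines by default; a continuity-constrained
variant (segments share their value at each breakpoint) is available.
The number of breakpoints is selected by BIC under a Gaussian error
model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import DataError, InfeasibleError

__all__ = ["SegmentedFit", "fit_segmented", "select_n_breaks"]

_MIN_SEG = 2  # observations per segment
_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class SegmentedFit:
    """Result of a segmented least-squares fit.

    breakpoints are reported midway between the observations they
    separate (e.g. a break between 2013 and 2014 is 2013.5).
    """

    breakpoints: tuple  # ordered, strictly inside the year range
    segment_coeffs: tuple  # per segment (intercept, slope)
    rss: float
    ic: float  # BIC
    n_obs: int

    @property
    def n_breaks(self) -> int:
        return len(self.breakpoints)

    def predict(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        out = np.empty_like(years)
        edges = (-np.inf,) + self.breakpoints + (np.inf,)
        for i, (a, b) in enumerate(self.segment_coeffs):
            m = (years > edges[i]) & (years <= edges[i + 1])
            out[m] = a + b * years[m]
        return out


def _validate_series(years, values):
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.ndim != 1 or years.shape != values.shape:
        raise DataError("series must be paired 1-d (year, value) vectors")
    if not np.all(np.diff(years) > 0):
        raise DataError("years must be sorted and distinct")
    return years, values


def _seg_rss(x, y):
    """OLS intercept/slope and RSS for one segment (n >= 2)."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx if sxx > 0 else 0.0
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    return (intercept, slope), float(resid @ resid)


def _bic(rss: float, n: int, n_breaks: int) -> float:
    k = 2 * (n_breaks + 1) + n_breaks
    return n * np.log(max(rss, _RSS_FLOOR) / n) + k * np.log(n)


def fit_segmented(years, values, n_breaks: int, continuous: bool = False) -> SegmentedFit:
    """Globally optimal piecewise-linear fit with ``n_breaks`` change points.

    Exhaustive search over all placements with at least two observations
    per segment; ties in RSS resolve to the first placement enumerated
    (leftmost breakpoints).
    """
    years, values = _validate_series(years, values)
    n = years.size
    if n < _MIN_SEG * (n_breaks + 1):
        raise InfeasibleError(
            f"{n} observations cannot support {n_breaks} breakpoints "
            f"(need >= {_MIN_SEG * (n_breaks + 1)})"
        )
    # cut after index i means the break lies between years[i] and years[i+1]
    cut_candidates = range(_MIN_SEG - 1, n - _MIN_SEG)
    best = None
    for cuts in itertools.combinations(cut_candidates, n_breaks):
        if any(b - a < _MIN_SEG for a, b in zip(cuts, cuts[1:])):
            continue
        bounds = (0,) + tuple(c + 1 for c in cuts) + (n,)
        if continuous:
            rss, coeffs = _continuous_fit(years, values, bounds)
        else:
            coeffs, rss = [], 0.0
            for lo, hi in zip(bounds, bounds[1:]):
                cf, r = _seg_rss(years[lo:hi], values[lo:hi])
                coeffs.append(cf)
                rss += r
        if best is None or rss < best[0] - 1e-15:
            bps = tuple(0.5 * (years[c] + years[c + 1]) for c in cuts)
            best = (rss, bps, tuple(coeffs))
    rss, bps, coeffs = best
    return SegmentedFit(
        breakpoints=bps,
        segment_coeffs=coeffs,
        rss=rss,
        ic=_bic(rss, n, n_breaks),
        n_obs=n,
    )


def _continuous_fit(years, values, bounds):
    """Least squares for a continuous piecewise-linear (broken-stick) model."""
    cuts = [0.5 * (years[b - 1] + years[b]) for b in bounds[1:-1]]
    X = [np.ones_like(years), years]
    for c in cuts:
        X.append(np.maximum(years - c, 0.0))
    X = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    rss = float(resid @ resid)
    # convert hinge coefficients to per-segment (intercept, slope)
    coeffs = []
    a, b = beta[0], beta[1]
    coeffs.append((a, b))
    for i, c in enumerate(cuts):
        a -= beta[2 + i] * c
        b += beta[2 + i]
        coeffs.append((a, b))
    return rss, coeffs


def select_n_breaks(years, values, max_breaks: int) -> int:
    """Number of breakpoints minimising BIC; ties resolve to fewer breaks."""
    years, values = _validate_series(years, values)
    if max_breaks < 0:
        raise DataError("max_breaks must be >= 0")
    n = years.size
    best_n, best_bic = 0, np.inf
    for nb in range(0, max_breaks + 1):
        if n < _MIN_SEG * (nb + 1):
            break  # feasibility limit for short series
        fit = fit_segmented(years, values, nb)
        if fit.ic < best_bic - 1e-12:
            best_bic, best_n = fit.ic, nb
    return best_n
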