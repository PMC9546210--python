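"""Size-frequency comparisons across the outbreak breakpoint.

Test diameters are recorded to the nearest centimetre, so samples arrive
either as raw per-individual sizes or as counts per 1-cm class; binned
data are expanded to bin-midpoint values before the two-sample
Kolmogorov–Smirnov comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError
from .growth import bin_midpoints

__all__ = ["SizeSample", "ks_two_sample", "weighted_mean_size"]


@dataclass(frozen=True)
class SizeSample:
    """Measured test diameters for one year: raw sizes or binned counts."""

    year: int
    sizes: np.ndarray | None = None  # cm, per individual
    counts: np.ndarray | None = None  # per 1-cm class
    bin_edges: np.ndarray | None = None  # length len(counts) + 1

    def __post_init__(self):
        if (self.sizes is None) == (self.counts is None):
            raise DataError("provide exactly one of sizes or counts")
        if self.sizes is not None:
            s = np.asarray(self.sizes, dtype=float)
            if s.size == 0:
                raise DataError("empty size sample")
            if np.any(s <= 0):
                raise DataError("sizes must be positive")
            object.__setattr__(self, "sizes", s)
        else:
            c = np.asarray(self.counts)
            if self.bin_edges is None or len(self.bin_edges) != c.size + 1:
                raise DataError("binned samples need bin_edges of length len(counts)+1")
            if np.any(c < 0) or c.sum() == 0:
                raise DataError("counts must be non-negative with positive total")
            object.__setattr__(self, "counts", np.asarray(c, dtype=np.int64))
            object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))

    def values(self) -> np.ndarray:
        """Per-individual sizes; binned counts expand to bin midpoints."""
        if self.sizes is not None:
            return self.sizes
        return np.repeat(bin_midpoints(self.bin_edges), self.counts)


def ks_two_sample(a: SizeSample, b: SizeSample) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| and asymptotic p."""
    res = stats.ks_2samp(a.values(), b.values(), method="asymp")
    return float(res.statistic), float(res.pvalue)


def weighted_mean_size(sample: SizeSample) -> float:
    """Count-weighted mean size (cm): sum_k midpoint_k * count_k / total."""
    v = sample.values()
    return float(v.mean())
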