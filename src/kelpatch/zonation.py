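"""Depth-zone and size-class assignment with density summaries.

The deep-reef recovery analysis bins survey sites into three depth zones
(shallow 0–6 m, mid 7–13 m, deep 14–20 m) and urchins into three
test-diameter classes (small <30 mm, medium 30–38 mm, large >38 mm),
then summarises mean densities with site-resampled bootstrap intervals.
Boundary closure (the 6–7 m and 13–14 m gaps; exactly 30 or 38 mm) is
fixed here: depths up to 6 m are shallow, up to 13 m mid, above deep;
30 mm and 38 mm are both medium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "DEPTH_ZONES",
    "SIZE_CLASSES",
    "assign_depth_zone",
    "assign_size_class",
    "zone_density_summary",
]

DEPTH_ZONES = ("shallow", "mid", "deep")
SIZE_CLASSES = ("small", "medium", "large")


def assign_depth_zone(depth_m: float) -> str:
    """Categorical depth zone for a site depth in metres (0–20)."""
    if not (0.0 <= depth_m <= 20.0):
        raise DataError(f"depth {depth_m} m outside the surveyed 0-20 m range")
    if depth_m <= 6.0:
        return "shallow"
    if depth_m <= 13.0:
        return "mid"
    return "deep"


def assign_size_class(diameter_mm: float) -> str:
    """Categorical size class for a test diameter in millimetres."""
    if not diameter_mm > 0:
        raise DataError("test diameter must be positive")
    if diameter_mm < 30.0:
        return "small"
    if diameter_mm <= 38.0:
        return "medium"
    return "large"


def zone_density_summary(
    records: pd.DataFrame,
    *,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Mean urchin density per year x depth zone x size class.

    ``records`` has one row per quadrat and size observation with columns
    site, year, quadrat, depth_m, size_mm, count (count may be 0 to
    register an empty quadrat).  Quadrats are 1 m^2, so per-quadrat
    counts are densities.  Intervals are seeded nonparametric bootstrap
    percentiles, resampling sites within each year x zone group; a group
    observed at a single site gets a degenerate interval.  Empty groups
    are simply absent from the output.
    """
    for col in ("site", "year", "quadrat", "depth_m", "size_mm", "count"):
        if col not in records.columns:
            raise DataError(f"missing column '{col}'")
    df = records.copy()
    df["zone"] = df["depth_m"].map(assign_depth_zone)
    df["size_class"] = [
        assign_size_class(s) if c > 0 else None
        for s, c in zip(df["size_mm"].fillna(1.0), df["count"])
    ]

    rng = np.random.default_rng(seed)
    alpha = 100 * (1 - level) / 2
    rows = []
    for (year, zone), grp in df.groupby(["year", "zone"], sort=True):
        # per-quadrat density per size class (zero-count rows register quadrats)
        all_quads = pd.MultiIndex.from_frame(
            grp[["site", "quadrat"]].drop_duplicates()
        )
        quad = (
            grp.dropna(subset=["size_class"])
            .pivot_table(
                index=["site", "quadrat"],
                columns="size_class",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(index=all_quads, fill_value=0)
            .reindex(columns=list(SIZE_CLASSES), fill_value=0)
        )
        sites = quad.index.get_level_values("site").to_numpy()
        uniq_sites = np.unique(sites)
        for sc in SIZE_CLASSES:
            dens = quad[sc].to_numpy(dtype=float)
            mean = dens.mean()
            if len(uniq_sites) > 1 and bootstrap_reps > 0:
                site_means = np.array(
                    [dens[sites == s].mean() for s in uniq_sites]
                )
                idx = rng.integers(0, len(uniq_sites), (bootstrap_reps, len(uniq_sites)))
                boots = site_means[idx].mean(axis=1)
                lo, hi = np.percentile(boots, [alpha, 100 - alpha])
            else:
                lo = hi = mean
            rows.append(
                {
                    "year": year,
                    "zone": zone,
                    "size_class": sc,
                    "mean": mean,
                    "lo95": lo,
                    "hi95": hi,
                    "n_quadrats": len(dens),
                    "n_sites": len(uniq_sites),
                }
            )
    return pd.DataFrame(rows)
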