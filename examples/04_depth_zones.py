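"""Depth-zone density summaries for the deep-reef recovery story.

Builds a small synthetic quadrat survey in which medium and large
urchins leave the deep zone and pile up in the shallows between 2018 and
2019, then summarises mean densities with site-bootstrap intervals.
"""

import numpy as np
import pandas as pd

import kelpatch as kp

rng = np.random.default_rng(0)
rows = []
# per-zone mean density (urchins per m^2 quadrat) by year for medium+large urchins
zone_depth = {"shallow": 4.0, "mid": 10.0, "deep": 17.0}
means = {
    2018: {"shallow": 1.5, "mid": 6.0, "deep": 9.0},
    2019: {"shallow": 14.0, "mid": 4.0, "deep": 1.0},
}
for year in (2018, 2019):
    for zone, depth in zone_depth.items():
        for s in range(6):
            for q in range(8):
                for mm in (25.0, 34.0, 45.0):
                    rows.append(
                        [f"{zone}{s}", year, q, depth, mm, rng.poisson(means[year][zone] / 3)]
                    )
records = pd.DataFrame(rows, columns=["site", "year", "quadrat", "depth_m", "size_mm", "count"])

summary = kp.zone_density_summary(records, bootstrap_reps=1000, seed=1)
print(summary.round(2).to_string(index=False))
print("\nLarge/medium density collapsing in the deep zone while rising inshore")
print("is the signature of urchins moving up-slope toward alternative food,")
print("which frees the deep reef for kelp recolonisation.")
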