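"""When did the outbreak start, and did the size structure change?

Runs segmented regression with BIC-selected change points on a simulated
annual density series, then compares the urchin size distribution across
the detected breakpoint with a two-sample Kolmogorov-Smirnov test.
"""

import numpy as np

import kelpatch as kp

sim = kp.simulate_population(kp.PopScenario(seed=3))

by_year = {}
for r in sim.observations:
    by_year.setdefault(r.year, []).append(r.counts.sum())
years = np.array(sorted(by_year))
dens = np.array([np.mean(by_year[y]) for y in years])

nb = kp.select_n_breaks(years, dens, max_breaks=3)
fit = kp.fit_segmented(years, dens, nb)
print(f"BIC selects {nb} change point(s); locations: {tuple(float(b) for b in fit.breakpoints)}")
print("A break at 2013.5 places the outbreak between the 2013 and 2014 surveys.")

edges = kp.default_bin_edges()
pooled = {y: sum(r.counts for r in sim.observations if r.year == y) for y in (2013, 2014)}
a = kp.SizeSample(year=2013, counts=pooled[2013], bin_edges=edges)
b = kp.SizeSample(year=2014, counts=pooled[2014], bin_edges=edges)
d, p = kp.ks_two_sample(a, b)
print(f"\nKS comparison 2013 vs 2014: D = {d:.3f} (p = {p:.3g})")
print(f"Count-weighted mean size: {kp.weighted_mean_size(a):.2f} cm (2013) "
      f"vs {kp.weighted_mean_size(b):.2f} cm (2014)")
print("A similar size distribution despite a jump in counts argues for a")
print("behavioural (visibility) shift rather than a recruitment pulse.")
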