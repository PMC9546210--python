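"""Did the urchin outbreak come from behaviour or demography?

Simulates a 23-year transect survey in which true detection probability
(urchins visible to divers) steps up 10-fold in 2014 while recruitment
doubles, fits the size-structured state-space model by MCMC, and asks
which process the posterior credits.
"""

import numpy as np

import kelpatch as kp
from kelpatch.popmodel import fold_change_summary, hindcast_density
from kelpatch.sensitivity import partition_increase

sim = kp.simulate_population(kp.PopScenario(seed=1))
print(f"{len(sim.observations)} transect records, years "
      f"{sim.latent.years[0]}-{sim.latent.years[-1]}")

samples = kp.fit_mcmc(sim.observations, seed=2, chains=2, draws=2000, warmup=3000, thin=2)
print(f"accept rate {samples.accept_rate:.2f}, converged={samples.converged}")

fc = fold_change_summary(samples, break_year=2013)
print("\nPosterior fold change after 2013 (mean [90% CI]; truth: 10, 2, 1):")
for proc in ("detection", "recruitment", "survival"):
    lo, hi = fc.interval(proc)
    print(f"  {proc:12s} {np.mean(fc.draws[proc]):6.2f}  [{lo:5.2f}, {hi:5.2f}]")

contrib = partition_increase(samples, break_year=2013)
print("\nShare of the observed post-2013 count increase (counterfactual partition):")
for proc, pct in contrib.mean_pct.items():
    print(f"  {proc:12s} {pct:6.1f} %")

h = hindcast_density(samples)
pre = h[h.year <= 2013]["mean"].mean()
post = h[h.year > 2013]["mean"].mean()
print(f"\nHindcast detected density per transect: {pre:.1f} pre-2014 vs {post:.1f} after")
print("A detection-dominated partition means the outbreak reflects urchins")
print("emerging from crevices, not a boom in recruitment or survival.")
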