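# kelpatch

Statistical machinery for asking how a kelp forest becomes an urchin
barren — and how it comes back.

Purple sea urchins (*Strongylocentrotus purpuratus*) switch between two
foraging modes: cryptic passive grazing on drift kelp from cracks and
crevices, and active grazing on live macroalgae out on open reef.  When
a regional outbreak of *visible* urchins appears in dive surveys, it can
mean two very different things: a demographic boom (recruitment,
survival) or a behavioural shift in which urchins already present simply
emerged from refuge and became countable.  `kelpatch` implements the
analysis chain needed to tell these apart and to characterise the
patchy forest/barren mosaic that follows:

* **`kelpatch.popmodel`** — a Bayesian size-structured state-space model
  of transect counts.  Latent densities `N[k, t]` in ten 1-cm
  test-diameter classes evolve by growth (a fixed von Bertalanffy
  transition matrix `G`), annual survival `s_t` and recruitment `R_t`
  into the smallest class:

      N[:, t] = s_t (Gᵀ N[:, t−1]) + R_t e₁

  Divers see only a fraction of the animals, so observed counts are
  negative-binomial around `λ[k, t] = p[k, t] · N[k, t]` with
  size-specific, year-varying detection probability `p` — the proxy for
  exposed vs concealed behaviour.  Baselines and hierarchical annual
  random effects for survival, recruitment and detection are estimated
  by MCMC (adaptive block Metropolis started at the posterior mode, 2+
  chains, split R-hat < 1.05 convergence rule), with posterior
  predictive checks, hindcast density bands and post-break **fold-change
  summaries** for each process.
* **`kelpatch.sensitivity`** — a simulation-based counterfactual
  partition: for each posterior draw, let one process keep its estimated
  year path while the other two stay at their pre-break baseline, and
  credit each process with its share of the post-break increase in
  detected density (shares sum to 100%).
* **`kelpatch.changepoint`** — exhaustive-search segmented regression
  with BIC-selected multiple change points for locating the outbreak
  year in annual density series.
* **`kelpatch.sizefreq`** — two-sample Kolmogorov–Smirnov comparison of
  annual size-frequency distributions and count-weighted mean sizes.
* **`kelpatch.patchstate`** — patch-state classification (two-class
  linear discriminant on urchin behaviour and algal cover), transition
  bookkeeping between consecutive years, IRLS logistic transition models
  with AICc selection, and 50%-probability **transition thresholds** in
  exposed-urchin density; distinct forward (forest→barren) and reverse
  (barren→forest) thresholds quantify hysteresis.
* **`kelpatch.zonation`** — depth-zone (shallow 0–6 m, mid 7–13 m, deep
  14–20 m) and size-class (<30, 30–38, >38 mm) assignment with
  site-bootstrap density summaries for the deep-reef recovery analysis.
* **`kelpatch.synth`** — generators for both survey schemas with known
  truth, so every stage is testable without field data.
* **`kelpatch.io`** — CSV readers/writers, YAML run configuration and an
  end-to-end pipeline; a thin `kelpatch` command-line wrapper covers the
  same steps (`kelpatch --help`).

## Worked example

`examples/01_behavioural_shift.py` simulates the study conditions — a
23-year survey whose true detection probability steps up 10-fold in 2014
while recruitment doubles — and fits the model:

```
138 transect records, years 1999-2021

Posterior fold change after 2013 (mean [90% CI]; truth: 10, 2, 1):
  detection      8.71  [ 5.92, 12.15]
  recruitment    1.98  [ 1.31,  2.82]
  survival       1.00  [ 0.99,  1.02]

Share of the observed post-2013 count increase (counterfactual partition):
  detection      92.2 %
  recruitment     6.9 %
  survival        1.0 %

Hindcast detected density per transect: 5.3 pre-2014 vs 76.0 after
```

The credible intervals recover the generating truth, and the partition
attributes nearly all of the fifteen-fold jump in *observed* density to
detection — i.e. to behaviour, not demography.  The other scripts in
`examples/` walk through change-point detection and size-frequency
comparison, patch classification with hysteresis thresholds (recovering
generating thresholds of 2.71 and 0.03 exposed urchins/m²), depth-zone
summaries, and the full YAML-configured pipeline.

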