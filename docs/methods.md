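# Methods

This note documents the models, default parameters, numerical choices
and known limitations of `kelpatch`.  Nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The size-structured state-space model

**Latent process.**  The population is tracked in S = 10 test-diameter
classes, half-open 1-cm bins [1,2) … [9,10) cm plus a ≥10 cm plus-group.
Given the state `N[:, t−1]` (density per transect), one year of dynamics
is

    N[:, t] = s_t · (Gᵀ N[:, t−1]) + R_t · e₁

where `G` is the growth transition matrix, `s_t ∈ (0,1)` annual
survival, and `R_t ≥ 0` recruits entering the smallest class only
(recruits are young-of-year by assumption).  The latent dynamics are
deterministic given the annual rates: all year-to-year process
variation is carried by the hierarchical year effects, with no
additional process noise.  That is a modelling assumption, made for
identifiability at the sample sizes involved, and it means credible
bands on the latent trajectory reflect parameter uncertainty only.

**Growth.**  `G` uses a Brody/von Bertalanffy mean increment: an
individual at bin midpoint `m` grows `max(0, (L∞ − m)(1 − e^(−k)))` cm
per year with Gaussian noise `σ`.  Mass below the source bin is
truncated (no shrinkage) and the remainder renormalised; the plus-group
absorbs.  Defaults `L∞ = 7 cm`, `k = 0.25 /yr`, `σ = 0.4 cm` are of the
magnitude reported in the tag-recapture literature for *S. purpuratus*;
they are configurable and not treated as ground truth.  A growth rate of
exactly zero is the degenerate no-growth case and returns the identity
matrix.

**Observation process.**  Expected counts are `λ[k,t] = p[k,t] · N[k,t]`
with detection probability `p` logit-linear in size-class index
(2 parameters) plus an annual deviation shared across classes; a fully
free per-class baseline (`detect_form="free"`) is available if the
size profile of detectability should not be constrained to a trend.
Counts are negative-binomial with dispersion φ (variance λ + λ²/φ),
the standard choice for clustered transect counts; Poisson is a config
option.  Whether the original analysis shared detection year effects
across classes is not knowable from the main text; sharing them is the
package default and the generator emulates that structure.

**Priors** (unconstrained scale; all in `ModelConfig.priors`):
detection intercept N(−1, 1.5), detection slope N(0, 1), survival logit
N(1, 1.5), log recruitment N(2.5, 2), log dispersion N(2, 1.5),
year-effect scales half-normal(1) via non-centred standardised effects,
log initial state N(2, 2) per class (a weak log-normal prior on the
first-year latent densities, which are free parameters).  Year-effect
vectors have one entry per study year; the survival and recruitment
entries for the first year have no transition to inform them and simply
shrink to the prior.

**Sampling.**  Fitting uses adaptive block random-walk Metropolis:
blocks for the global parameters, each year-effect vector, the initial
state, and one joint block over all parameters whose adapted covariance
can traverse the ridge between overall detection level and latent
abundance (`λ = p·N` identifies only the product when detection is
small).  Chains start at the BFGS posterior mode with proposal
covariances seeded from the BFGS inverse Hessian (a Laplace
approximation); per-block scales follow Robbins–Monro adaptation toward
25% acceptance during warmup and are frozen afterwards, so the
post-warmup chain has the correct invariant distribution.  The
posterior support is truncated at |θ| > 60 on the unconstrained scale,
far outside any prior mass, to keep every exponential finite.  Split
R-hat (arviz) is reported per parameter and the fit is flagged
converged only when all are below 1.05.  Two chains of 3000 warmup +
2500 kept draws (thin 2) — about 20 s per fit — are enough for
well-calibrated fold-change intervals (the acceptance suite measures
90% interval coverage of 17/20, 17/20 and 19/20 for the three
processes), but R-hat typically remains in the 1.2–2 range at that
length: the convergence flag is honest about it, and halving it
requires several-fold longer chains.

**Summaries.**  Fold changes divide the posterior mean process value
averaged over post-break years (calendar year > 2013, i.e. 2014 onward)
by the pre-break average; detection is averaged over the "large" classes
(lower bin edge ≥ 3 cm, matching an adult (>3 cm) count criterion), and
survival/recruitment use arrival years only.  Hindcasts report the
posterior mean and central 90% interval of Σ_k λ[k,t].  Posterior
predictive checks simulate replicate surveys per draw and report, per
year, Pr(replicate > observed) with half mass on ties for two
statistics: mean per-transect total count and count-weighted mean size.

## Counterfactual variance partition

"Contribution" has no unique definition; the package adopts the
one-varies scheme: for each draw, simulate the trajectory in which one
process follows its estimated year path while the other two sit at
their pre-break means (natural scale), take that counterfactual's
post-minus-pre increase in mean detected density, and normalise the
three increases to 100%.  Draws in which no counterfactual shows an
increase are flagged and excluded from the normalisation (their count
is reported).  A leave-one-out alternative (`scheme="leave_one_out"`,
contribution = full increase minus the increase with that process
frozen) is provided as a robustness check; both sum to 100% by
construction, and a process with a flat year path contributes zero
provided the initial state is at the pre-break equilibrium.

## Changepoint selection

Annual series are ≤ 23 points, so breakpoint placement is globally
optimal by exhaustive enumeration over between-observation positions
with at least two observations per segment; breakpoints are reported at
the midpoint of the straddled years (a break between the 2013 and 2014
surveys is 2013.5).  Segments are independent lines by default — the
field's "segmented regression" is ambiguous about continuity — with a
continuity-constrained broken-stick variant available.  The number of
breaks minimises BIC, `n·log(RSS/n) + k·log n` with
`k = 2(n_breaks+1) + n_breaks`; RSS is floored at 1e−12 so that
noiseless series resolve ties toward fewer breaks.

## Size-frequency comparison

Sizes recorded to the nearest centimetre arrive as binned counts; these
expand to bin midpoints before the two-sample KS test (scipy, asymptotic
p-value — yearly samples are large; the heavy tying from 1-cm rounding
makes the p-value conservative, while D itself is exact for the
midpoint representation).

## Patch-state analysis

**Classifier.**  A two-class Gaussian discriminant with pooled
within-class covariance on six features: exposed density, concealed
density, and the four indicator algal cover fractions (articulated
coralline, encrusting coralline + red, brown, foliose red).  Total
density is excluded because it is the exact sum of the two behaviour
densities and would make the pooled covariance singular.  Class priors
default to empirical frequencies.  A singular covariance triggers ridge
regularisation with a warning.  Training reports the resubstitution
misclassification count and an entropy R², defined as McFadden's
likelihood-ratio R² of the label likelihood.  An exact posterior tie
classifies as forest.

**Transitions.**  Only sites surveyed at the same location in
consecutive years are paired; each pair yields exactly one record with
outcome 1 for a state change.  Exposed density enters models as
ln(x + c) with c set to half the minimum nonzero observed density
(configurable) to handle zeros.

**Logistic models.**  IRLS to a 1e−8 coefficient tolerance; complete
separation is flagged (diverging coefficients), not raised.  AICc
`= −2ℓ + 2p + 2p(p+1)/(n−p−1)` drives model selection with first-listed
winners on exact ties.  The 50% threshold solves the linear predictor
for zero on the log scale with other covariates at their
state-conditional means (the start-state dummy at its value, concealed
density at the within-state mean), then back-transforms and subtracts
c; thresholds outside the observed density range for that state carry
an extrapolation flag.

## Depth zonation

Stated zone bounds (0–6, 7–13, 14–20 m) leave the 6–7 and 13–14 m gaps
open, and the size bounds leave 30 and 38 mm ambiguous; the package
fixes upper-inclusive closures: depth ≤ 6 shallow, ≤ 13 mid, else deep;
30 mm and 38 mm are both medium.  Density summaries bootstrap sites
(the independent sampling unit) within year × zone, with percentile 95%
intervals; groups with one site get degenerate intervals and empty
groups are absent, not zero.

## Synthetic generators

`simulate_population` defaults encode the study conditions: 23 annual
surveys (1999–2021), six transects per year, negative-binomial counts
with φ = 10, flat survival 0.85, recruitment stepping 15 → 30 per
transect and detection stepping 0.05 → 0.5 (a 10-fold behavioural
emergence) in 2014, with the initial state from a 50-year burn-in at
the pre-break rates.  `simulate_mosaic` defaults to 300 sites over
2017–2019, 16 one-m² quadrats per site, logistic transition rules on
ln exposed density with true thresholds at 2.71 (forward, slope 2.2)
and 0.03 urchins/m² (reverse, slope −1.3), state-conditional lognormal
densities — barren exposed densities heavy-tailed (σ_ln = 2.5) so both
tails overlap the thresholds and the transition rules are identifiable
at the design size — Dirichlet-multinomial cover compositions (four
indicator groups plus bare substrate, so covers sum to ≤ 1), and a 2%
field-label noise rate.  Both generators are pure functions of their
scenario including its mandatory seed.

What the generators do *not* emulate: spatial autocorrelation among
sites, observer differences, size-measurement error, episodic
multi-year recruitment pulses, and any feedback of patch state onto
demography.  Passing recovery tests therefore demonstrates the
estimators' correctness and calibration under the stated model, not
robustness to field-data pathologies.

## Numerical notes and limitations

* All randomness flows through explicit integer seeds
  (`numpy.random.SeedSequence` spawning per chain); repeated runs are
  bit-identical.
* The negative-binomial log-likelihood is computed from per-year
  sufficient summaries and the unique observed counts, which makes a
  full model evaluation ~50 µs and the quoted MCMC lengths practical.
* Fold-change and partition summaries are ratios of posterior paths and
  are insensitive to the detection-level/abundance ridge; absolute
  detection probabilities and absolute latent densities are only weakly
  identified when detection is small, and their marginals lean on the
  priors.
* `threshold_50` extrapolates outside the fitted density range when the
  crossing lies there; the flag should be checked before ecological
  interpretation.
* The REML mixed-model and contrast-test stage of a full deep-reef
  recovery analysis is out of scope; `zonation` supplies the
  categorical assignments and bootstrap summaries that feed it.
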