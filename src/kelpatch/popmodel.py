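"""Bayesian size-structured state-space model of urchin transect counts.

The latent population tracks densities in S one-centimetre test-diameter
classes (default ``[1,2), ..., [9,10), [10,inf)`` cm) across the study
years.  Three demographic processes drive the latent dynamics — annual
growth (a fixed transition matrix), survival, and recruitment into the
smallest class — while a fourth, observer-side process, size-specific
detection probability, links the latent state to the counts divers record
on transects:

    N[:, t] = s_t * (G' N[:, t-1]) + R_t e_1
    lambda[k, t] = p_detect[k, t] * N[k, t]
    y ~ NegBin(mean=lambda, dispersion=phi)     (Poisson optional)

Survival, recruitment and detection each have a baseline plus hierarchical
year-to-year random effects (non-centred; half-normal hyper-scales).
Detection is logit-linear in size-class index by default with a shared
annual deviation.  Fitting is by adaptive block random-walk Metropolis
with 2+ chains; convergence is flagged when every parameter's split
R-hat is below 1.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from ._sampler import run_chain
from .errors import DataError, DimensionError, InvalidParamsError
from .growth import GrowthMatrix, GrowthParams, bin_midpoints, build_growth_matrix

__all__ = [
    "SizeFrequency",
    "ModelConfig",
    "DemographicParams",
    "LatentPopulation",
    "PosteriorSamples",
    "FoldChangeSummary",
    "default_bin_edges",
    "project_population",
    "expected_counts",
    "log_likelihood",
    "fit_mcmc",
    "posterior_predictive_check",
    "hindcast_density",
    "fold_change_summary",
]

RHAT_THRESHOLD = 1.05


def default_bin_edges() -> np.ndarray:
    """Half-open 1-cm bins [1,2)..[9,10) plus a >=10 cm plus-group."""
    return np.append(np.arange(1.0, 11.0), np.inf)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SizeFrequency:
    """Counts of urchins per size class on one transect in one year."""

    year: int
    site_id: str
    transect_id: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise DataError("counts must be a 1-d vector")
        if not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.floor(c)):
                raise DataError("counts must be integers")
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise DataError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))


@dataclass
class ModelConfig:
    """Model structure, priors and conventions.

    priors maps name -> (mean, sd) for normal priors on the unconstrained
    scale, except 'sd_halfnormal' which is the half-normal scale of the
    hierarchical year-effect SDs.
    """

    bin_edges: np.ndarray = field(default_factory=default_bin_edges)
    growth: GrowthParams = field(
        default_factory=lambda: GrowthParams(
            asymptotic_size=7.0, growth_rate=0.25, increment_sd=0.4
        )
    )
    family: str = "negbin"  # or "poisson"
    detect_form: str = "linear"  # or "free" (one logit baseline per class)
    break_year: int = 2013
    large_min_cm: float = 3.0
    priors: dict = field(
        default_factory=lambda: {
            "detect_intercept": (-1.0, 1.5),
            "detect_slope": (0.0, 1.0),
            "logit_surv": (1.0, 1.5),
            "log_recruit": (2.5, 2.0),
            "log_phi": (2.0, 1.5),
            "sd_halfnormal": 1.0,
            "log_init": (2.0, 2.0),
        }
    )

    @property
    def n_classes(self) -> int:
        return len(self.bin_edges) - 1

    def growth_matrix(self) -> GrowthMatrix:
        return build_growth_matrix(self.growth, self.bin_edges)

    def large_classes(self) -> np.ndarray:
        """Boolean mask of the 'large urchin' classes (lower edge >= large_min_cm)."""
        return np.asarray(self.bin_edges[:-1]) >= self.large_min_cm


@dataclass
class DemographicParams:
    """One full set of demographic/observation parameters.

    Year effects are additive deviations on the linked scale (logit for
    survival and detection, log for recruitment), one entry per study
    year; survival/recruitment effects for the first year are inert (no
    transition leads into it).  ``log_init`` is the latent log density per
    class in the first study year.
    """

    recruit_base: float
    surv_base: float
    detect_base: np.ndarray  # (S,) logit baseline detection per class
    year_fx_recruit: np.ndarray  # (T,)
    year_fx_surv: np.ndarray  # (T,)
    year_fx_detect: np.ndarray  # (T,)
    sd_recruit: float
    sd_surv: float
    sd_detect: float
    overdispersion: float
    log_init: np.ndarray  # (S,)

    def validate(self) -> None:
        for name in ("sd_recruit", "sd_surv", "sd_detect", "overdispersion"):
            if not getattr(self, name) > 0:
                raise InvalidParamsError(f"{name} must be > 0")
        T = len(self.year_fx_detect)
        if not (len(self.year_fx_recruit) == len(self.year_fx_surv) == T):
            raise InvalidParamsError("year-effect vectors must share one entry per study year")
        if len(self.detect_base) != len(self.log_init):
            raise InvalidParamsError("detect_base and log_init must have one entry per class")

    # linked-scale -> natural-scale paths
    def detection(self) -> np.ndarray:
        """(S, T) detection probabilities."""
        return expit(np.asarray(self.detect_base)[:, None] + np.asarray(self.year_fx_detect)[None, :])

    def survival(self) -> np.ndarray:
        """(T,) annual survival; entry t applies to the t-1 -> t transition."""
        return expit(self.surv_base + np.asarray(self.year_fx_surv))

    def recruitment(self) -> np.ndarray:
        """(T,) recruits per transect arriving in year t."""
        return np.exp(self.recruit_base + np.asarray(self.year_fx_recruit))


@dataclass(frozen=True)
class LatentPopulation:
    """True (unobserved) density per size class and year."""

    N: np.ndarray  # (S, T)
    years: np.ndarray

    def __post_init__(self):
        N = np.asarray(self.N, dtype=float)
        if N.ndim != 2:
            raise DimensionError("N must be S x T")
        if np.any(N < 0):
            raise InvalidParamsError("latent densities must be non-negative")
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "years", np.asarray(self.years))


# ---------------------------------------------------------------------------
# deterministic process operations


def project_population(
    N_t: np.ndarray, G: GrowthMatrix, survival_t: float, recruits_t: float
) -> np.ndarray:
    """One-year projection: grow survivors, then add recruits to class 1."""
    N_t = np.asarray(N_t, dtype=float)
    if np.any(N_t < 0) or not (0.0 <= survival_t <= 1.0) or recruits_t < 0:
        raise InvalidParamsError(
            "densities must be >= 0, survival in [0,1], recruits >= 0"
        )
    if N_t.shape != (G.n_classes,):
        raise DimensionError("N_t length must equal the number of size classes")
    out = survival_t * (N_t @ G.probs)
    out[0] += recruits_t
    return out


def _forward_latent(
    N0: np.ndarray, G: np.ndarray, surv: np.ndarray, recruit: np.ndarray
) -> np.ndarray:
    """Latent trajectory (..., S, T) from initial state and annual paths.

    Batched: N0 (..., S), surv/recruit (..., T).  Entry 0 of surv/recruit
    is unused (no transition into the first year).
    """
    N0 = np.asarray(N0, dtype=float)
    T = surv.shape[-1]
    out = np.empty(N0.shape + (T,))
    out[..., 0] = N0
    for t in range(1, T):
        nxt = surv[..., t, None] * (out[..., t - 1] @ G)
        nxt[..., 0] += recruit[..., t]
        out[..., t] = nxt
    return out


def expected_counts(N, detect: np.ndarray) -> np.ndarray:
    """Expected observed counts lambda[k, t] = detect[k, t] * N[k, t]."""
    arr = N.N if isinstance(N, LatentPopulation) else np.asarray(N, dtype=float)
    detect = np.asarray(detect, dtype=float)
    if detect.shape != arr.shape:
        raise DimensionError(
            f"detection shape {detect.shape} does not match latent shape {arr.shape}"
        )
    if np.any((detect < 0) | (detect > 1)):
        raise InvalidParamsError("detection probabilities must lie in [0,1]")
    return detect * arr


# ---------------------------------------------------------------------------
# data preparation and count likelihood


class _PreparedData:
    """Sufficient summaries of a SizeFrequency collection for fast likelihoods."""

    def __init__(self, data: Sequence[SizeFrequency], S: int):
        if len(data) == 0:
            raise DataError("empty data collection")
        for rec in data:
            if len(rec.counts) != S:
                raise DataError(
                    f"record {rec.site_id}/{rec.transect_id}/{rec.year} has "
                    f"{len(rec.counts)} classes, expected {S}"
                )
        years = np.array(sorted({rec.year for rec in data}))
        if np.any(np.diff(years) != 1):
            raise DataError("data years must be contiguous")
        self.years = years
        T = len(years)
        yindex = {y: t for t, y in enumerate(years)}
        self.Ysum = np.zeros((S, T))
        self.m = np.zeros(T)
        all_counts = []
        for rec in data:
            t = yindex[rec.year]
            self.Ysum[:, t] += rec.counts
            self.m[t] += 1
            all_counts.append(rec.counts)
        y = np.concatenate(all_counts)
        self.n_cells = y.size
        self.const = -float(gammaln(y + 1).sum())
        self.uniq, self.uniq_n = np.unique(y, return_counts=True)
        self.mean_total_per_year = self.Ysum.sum(axis=0) / self.m

    def count_loglik(self, lam: np.ndarray, phi: float, family: str) -> float:
        """Sum of count log-pmfs over every transect/year/class cell."""
        lam = np.maximum(lam, 1e-300)
        if family == "poisson":
            ll = -(self.m[None, :] * lam).sum() + (self.Ysum * np.log(lam)).sum()
            return float(ll + self.const)
        # negative binomial, mean lam, Var = lam + lam^2/phi
        t3 = (
            self.m[None, :] * phi * np.log(phi / (phi + lam))
            + self.Ysum * np.log(lam / (phi + lam))
        ).sum()
        t1 = float((self.uniq_n * gammaln(self.uniq + phi)).sum())
        t2 = -self.n_cells * float(gammaln(phi))
        return float(t1 + t2 + t3 + self.const)


def log_likelihood(
    params: DemographicParams,
    data: Sequence[SizeFrequency],
    G: GrowthMatrix,
    family: str = "negbin",
) -> float:
    """Log-likelihood of a SizeFrequency collection under the state-space model."""
    params.validate()
    prep = _PreparedData(data, G.n_classes)
    T = len(prep.years)
    if len(params.year_fx_detect) != T:
        raise InvalidParamsError("year-effect length does not match the data years")
    N = _forward_latent(
        np.exp(np.asarray(params.log_init, dtype=float)),
        G.probs,
        params.survival(),
        params.recruitment(),
    )
    lam = params.detection() * N
    return prep.count_loglik(lam, params.overdispersion, family)


# ---------------------------------------------------------------------------
# parameter vector layout for MCMC


class _Layout:
    def __init__(self, S: int, T: int, detect_form: str):
        self.S, self.T, self.detect_form = S, T, detect_form
        names: list[str] = []
        self.slices: dict[str, slice] = {}

        def add(name, labels):
            start = len(names)
            names.extend(labels)
            self.slices[name] = slice(start, len(names))

        if detect_form == "linear":
            add("detect_base", ["detect_intercept", "detect_slope"])
        elif detect_form == "free":
            add("detect_base", [f"detect_base[{k}]" for k in range(S)])
        else:
            raise InvalidParamsError(f"unknown detect_form {detect_form!r}")
        add("logit_surv", ["logit_surv"])
        add("log_recruit", ["log_recruit"])
        add("log_phi", ["log_phi"])
        add("z_detect", [f"z_detect[{t}]" for t in range(T)])
        add("z_surv", [f"z_surv[{t}]" for t in range(T)])
        add("z_recruit", [f"z_recruit[{t}]" for t in range(T)])
        add("log_sd", ["log_sd_detect", "log_sd_surv", "log_sd_recruit"])
        add("log_init", [f"log_init[{k}]" for k in range(S)])
        self.names = names
        self.P = len(names)

    def blocks(self) -> list[np.ndarray]:
        s = self.slices
        globals_idx = np.r_[
            np.arange(s["detect_base"].start, s["detect_base"].stop),
            np.arange(s["logit_surv"].start, s["logit_surv"].stop),
            np.arange(s["log_recruit"].start, s["log_recruit"].stop),
            np.arange(s["log_phi"].start, s["log_phi"].stop),
            np.arange(s["log_sd"].start, s["log_sd"].stop),
        ]
        return [
            globals_idx,
            np.arange(s["z_detect"].start, s["z_detect"].stop),
            np.arange(s["z_surv"].start, s["z_surv"].stop),
            np.arange(s["z_recruit"].start, s["z_recruit"].stop),
            np.arange(s["log_init"].start, s["log_init"].stop),
            # joint block over everything: its adapted covariance learns the
            # detection-level / latent-abundance ridge that the smaller
            # blocks cannot traverse
            np.arange(self.P),
        ]

    def detect_logits(self, theta: np.ndarray) -> np.ndarray:
        """(..., S) baseline detection logits from the packed vector."""
        base = theta[..., self.slices["detect_base"]]
        if self.detect_form == "free":
            return base
        k = np.arange(self.S) - (self.S - 1) / 2.0
        return base[..., :1] + base[..., 1:2] * k


def _unpack_paths(theta: np.ndarray, lay: _Layout):
    """Natural-scale paths from packed parameters; theta may be batched (..., P)."""
    s = lay.slices
    sd = np.exp(theta[..., s["log_sd"]])
    detect = expit(
        lay.detect_logits(theta)[..., :, None]
        + (sd[..., 0:1] * theta[..., s["z_detect"]])[..., None, :]
    )
    surv = expit(theta[..., s["logit_surv"]] + sd[..., 1:2] * theta[..., s["z_surv"]])
    recruit = np.exp(theta[..., s["log_recruit"]] + sd[..., 2:3] * theta[..., s["z_recruit"]])
    phi = np.exp(theta[..., s["log_phi"]])[..., 0]
    N0 = np.exp(theta[..., s["log_init"]])
    return detect, surv, recruit, phi, N0


def _make_logpost(prep: _PreparedData, config: ModelConfig, lay: _Layout):
    G = config.growth_matrix().probs
    pri = config.priors
    s = lay.slices
    if lay.detect_form == "linear":
        det_mu = np.array([pri["detect_intercept"][0], pri["detect_slope"][0]])
        det_sd = np.array([pri["detect_intercept"][1], pri["detect_slope"][1]])
    else:
        det_mu = np.full(lay.S, pri["detect_intercept"][0])
        det_sd = np.full(lay.S, pri["detect_intercept"][1])
    hn = pri["sd_halfnormal"]

    def logpost(theta: np.ndarray) -> float:
        # truncate the far tails (priors put ~zero mass there); this keeps
        # every downstream exp()/log() finite
        if np.max(np.abs(theta)) > 60.0:
            return -np.inf
        detect, surv, recruit, phi, N0 = _unpack_paths(theta, lay)
        N = _forward_latent(N0, G, surv, recruit)
        ll = prep.count_loglik(detect * N, phi, config.family)
        lp = ll
        lp += -0.5 * np.sum(((theta[s["detect_base"]] - det_mu) / det_sd) ** 2)
        mu, sig = pri["logit_surv"]
        lp += -0.5 * ((theta[s["logit_surv"]][0] - mu) / sig) ** 2
        mu, sig = pri["log_recruit"]
        lp += -0.5 * ((theta[s["log_recruit"]][0] - mu) / sig) ** 2
        mu, sig = pri["log_phi"]
        lp += -0.5 * ((theta[s["log_phi"]][0] - mu) / sig) ** 2
        for zname in ("z_detect", "z_surv", "z_recruit"):
            lp += -0.5 * np.sum(theta[s[zname]] ** 2)
        # half-normal on sds, with log-scale Jacobian
        lsd = theta[s["log_sd"]]
        lp += np.sum(-0.5 * (np.exp(lsd) / hn) ** 2 + lsd)
        mu, sig = pri["log_init"]
        lp += -0.5 * np.sum(((theta[s["log_init"]] - mu) / sig) ** 2)
        return float(lp) if np.isfinite(lp) else -np.inf

    return logpost


def _initial_point(prep: _PreparedData, config: ModelConfig, lay: _Layout) -> np.ndarray:
    """Moment-flavoured starting point: assume modest detection, back out N."""
    x = np.zeros(lay.P)
    s = lay.slices
    p0 = 0.2
    if lay.detect_form == "linear":
        x[s["detect_base"]] = [logit(p0), 0.0]
    else:
        x[s["detect_base"]] = logit(p0)
    x[s["logit_surv"]] = 1.0
    S = lay.S
    first_year_mean = prep.Ysum[:, 0] / prep.m[0]
    x[s["log_init"]] = np.log(np.maximum(first_year_mean / p0, 0.5))
    x[s["log_recruit"]] = np.log(max(prep.mean_total_per_year.mean() / p0 * 0.15, 1.0))
    x[s["log_phi"]] = np.log(10.0)
    x[s["log_sd"]] = np.log(0.5)
    return x


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Posterior draws with derived demographic paths.

    Array layout: theta (chains, draws, P); derived arrays are flattened
    over chains*draws in their leading dimension.
    """

    years: np.ndarray
    config: ModelConfig
    G: np.ndarray  # (S, S) growth transition probabilities
    N: np.ndarray  # (B, S, T) latent densities
    detect: np.ndarray  # (B, S, T)
    surv: np.ndarray  # (B, T); entry 0 inert
    recruit: np.ndarray  # (B, T); entry 0 inert
    phi: np.ndarray  # (B,)
    theta: np.ndarray | None = None  # (chains, draws, P)
    param_names: list[str] | None = None
    rhat: dict | None = None
    converged: bool = False
    accept_rate: float | None = None

    @property
    def n_draws(self) -> int:
        return self.N.shape[0]

    def lam(self) -> np.ndarray:
        """(B, S, T) expected detected density per transect."""
        return self.detect * self.N

    @classmethod
    def from_paths(
        cls,
        *,
        years,
        config: ModelConfig,
        detect: np.ndarray,
        surv: np.ndarray,
        recruit: np.ndarray,
        N0: np.ndarray,
        phi,
    ) -> "PosteriorSamples":
        """Build a sample container directly from demographic paths.

        Accepts unbatched arrays (S,T)/(T,)/(S,) for a single 'draw' or
        batched arrays with a leading draw dimension.  Used for
        counterfactual work and tests.
        """
        detect = np.asarray(detect, dtype=float)
        if detect.ndim == 2:
            detect = detect[None]
            surv = np.asarray(surv, dtype=float)[None]
            recruit = np.asarray(recruit, dtype=float)[None]
            N0 = np.asarray(N0, dtype=float)[None]
        surv = np.asarray(surv, dtype=float)
        recruit = np.asarray(recruit, dtype=float)
        N0 = np.asarray(N0, dtype=float)
        phi = np.broadcast_to(np.asarray(phi, dtype=float), (detect.shape[0],)).copy()
        G = config.growth_matrix().probs
        N = _forward_latent(N0, G, surv, recruit)
        return cls(
            years=np.asarray(years),
            config=config,
            G=G,
            N=N,
            detect=detect,
            surv=surv,
            recruit=recruit,
            phi=phi,
        )


# ---------------------------------------------------------------------------
# fitting


def fit_mcmc(
    data: Sequence[SizeFrequency],
    config: ModelConfig | None = None,
    *,
    seed: int,
    chains: int = 2,
    draws: int = 1500,
    warmup: int = 1500,
    thin: int = 1,
) -> PosteriorSamples:
    """Fit the state-space model by adaptive block Metropolis MCMC.

    Deterministic given ``seed``.  Non-convergence (any split R-hat >=
    1.05) is flagged on the returned object, never raised.
    """
    if chains < 2:
        raise InvalidParamsError("at least 2 chains are required")
    if draws <= 0 or warmup <= 0 or thin <= 0:
        raise InvalidParamsError("draws, warmup and thin must be positive")
    config = config or ModelConfig()
    prep = _PreparedData(data, config.n_classes)
    lay = _Layout(config.n_classes, len(prep.years), config.detect_form)
    logpost = _make_logpost(prep, config, lay)
    x0 = _initial_point(prep, config, lay)
    blocks = lay.blocks()

    # Start chains at the (approximate) posterior mode and seed the proposal
    # covariances from the BFGS inverse Hessian (a Laplace approximation),
    # so warmup refines rather than discovers the posterior geometry.
    from scipy.optimize import minimize

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        opt = minimize(
            lambda th: min(-logpost(th), 1e300),
            x0,
            method="BFGS",
            options={"maxiter": 500},
        )
    if np.all(np.isfinite(opt.x)) and np.isfinite(logpost(opt.x)):
        x0 = opt.x
    cov = np.asarray(opt.hess_inv)
    if not np.all(np.isfinite(cov)):
        cov = np.eye(lay.P) * 0.01
    cov = 0.5 * (cov + cov.T)
    init_chols = []
    for idx in blocks:
        sub = cov[np.ix_(idx, idx)]
        sub = sub + np.eye(len(idx)) * (1e-8 + 1e-6 * np.trace(sub) / len(idx))
        try:
            init_chols.append(np.linalg.cholesky(sub))
        except np.linalg.LinAlgError:
            init_chols.append(None)

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(chains)]
    all_draws = np.empty((chains, draws, lay.P))
    acc = []
    for c, rng in enumerate(rngs):
        start = x0 + 0.05 * rng.standard_normal(lay.P)
        ch, a = run_chain(
            logpost,
            start,
            blocks,
            n_warmup=warmup,
            n_draws=draws,
            thin=thin,
            rng=rng,
            init_chols=init_chols,
        )
        all_draws[c] = ch
        acc.append(a)

    rhat = _split_rhat(all_draws, lay.names)
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(finite) and max(finite) < RHAT_THRESHOLD

    flat = all_draws.reshape(-1, lay.P)
    detect, surv, recruit, phi, N0 = _unpack_paths(flat, lay)
    N = _forward_latent(N0, config.growth_matrix().probs, surv, recruit)
    return PosteriorSamples(
        years=prep.years,
        config=config,
        G=config.growth_matrix().probs,
        N=N,
        detect=detect,
        surv=surv,
        recruit=recruit,
        phi=phi,
        theta=all_draws,
        param_names=lay.names,
        rhat=rhat,
        converged=converged,
        accept_rate=float(np.mean(acc)),
    )


def _split_rhat(draws: np.ndarray, names: list[str]) -> dict:
    """Split R-hat per parameter via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({"theta": draws})
        r = np.asarray(az.rhat(ds)["theta"])
    return dict(zip(names, r.tolist()))


# ---------------------------------------------------------------------------
# posterior summaries


def posterior_predictive_check(
    samples: PosteriorSamples,
    data: Sequence[SizeFrequency],
    *,
    seed: int = 0,
    max_draws: int = 400,
) -> dict:
    """Bayesian p-values for two check statistics, per year.

    Statistics: mean per-transect total count, and count-weighted mean
    size.  The p-value is Pr(replicate > observed) with half mass on
    ties; years with zero observed total have an undefined mean size
    (NaN).
    """
    prep = _PreparedData(data, samples.config.n_classes)
    if not np.array_equal(prep.years, samples.years):
        raise DataError("data years do not match the fitted years")
    mids = bin_midpoints(samples.config.bin_edges)
    rng = np.random.default_rng(seed)
    B = samples.n_draws
    take = np.linspace(0, B - 1, min(max_draws, B)).astype(int)
    lam = samples.lam()[take]
    phi = samples.phi[take]
    T = len(prep.years)
    m = prep.m.astype(int)

    obs_total = prep.Ysum.sum(axis=0) / prep.m
    tot_obs = prep.Ysum.sum(axis=0)
    with np.errstate(invalid="ignore"):
        obs_msize = (mids @ prep.Ysum) / tot_obs

    rep_total = np.empty((len(take), T))
    rep_msize = np.empty((len(take), T))
    for d in range(len(take)):
        for t in range(T):
            mu = np.repeat(lam[d, :, t][None, :], m[t], axis=0)
            if samples.config.family == "poisson":
                y = rng.poisson(mu)
            else:
                p = phi[d] / (phi[d] + np.maximum(mu, 1e-300))
                y = rng.negative_binomial(phi[d], p)
            rep_total[d, t] = y.sum() / m[t]
            tot = y.sum()
            rep_msize[d, t] = (mids @ y.sum(axis=0)) / tot if tot > 0 else np.nan

    def pval(rep, obs):
        valid = ~np.isnan(rep)
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            gt = np.nansum(rep > obs[None, :], axis=0)
            eq = np.nansum(rep == obs[None, :], axis=0)
            return np.where(n > 0, (gt + 0.5 * eq) / np.maximum(n, 1), np.nan)

    return {
        "total_count": pval(rep_total, obs_total),
        "mean_size": np.where(
            np.isnan(obs_msize), np.nan, pval(rep_msize, obs_msize)
        ),
        "years": prep.years,
    }


def hindcast_density(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-year posterior mean and central 90% interval of detected density."""
    total = samples.lam().sum(axis=1)  # (B, T)
    lo, hi = np.percentile(total, [5.0, 95.0], axis=0)
    return pd.DataFrame(
        {
            "year": samples.years,
            "mean": total.mean(axis=0),
            "lo90": lo,
            "hi90": hi,
        }
    )


@dataclass(frozen=True)
class FoldChangeSummary:
    """Posterior fold changes (post/pre break) per demographic process."""

    draws: dict  # process -> (B,) fold-change draws
    break_year: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for proc, d in self.draws.items():
            lo, hi = np.percentile(d, [5.0, 95.0])
            rows.append(
                {"process": proc, "mean": d.mean(), "q5": lo, "q50": np.median(d), "q95": hi}
            )
        return pd.DataFrame(rows)

    def interval(self, process: str, level: float = 0.90) -> tuple[float, float]:
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.draws[process], [a, 100 - a])
        return float(lo), float(hi)


def fold_change_summary(samples: PosteriorSamples, break_year: int) -> FoldChangeSummary:
    """Fold change of each process: mean over post-break years / pre-break years.

    Detection is averaged over the configured 'large' size classes;
    survival and recruitment use arrival years (the first study year has
    no transition into it).
    """
    years = samples.years
    pre = years <= break_year
    post = years > break_year
    pre_arr = pre.copy()
    pre_arr[0] = False  # no transition into the first year
    if not pre_arr.any() or not post.any():
        raise InvalidParamsError(
            f"break year {break_year} leaves an empty pre or post window"
        )
    large = samples.config.large_classes()

    det = samples.detect[:, large, :].mean(axis=1)  # (B, T)
    draws = {
        "detection": det[:, post].mean(axis=1) / det[:, pre].mean(axis=1),
        "recruitment": samples.recruit[:, post].mean(axis=1)
        / samples.recruit[:, pre_arr].mean(axis=1),
        "survival": samples.surv[:, post].mean(axis=1)
        / samples.surv[:, pre_arr].mean(axis=1),
    }
    return FoldChangeSummary(draws=draws, break_year=break_year)
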