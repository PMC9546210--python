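"""Synthetic-data generators with known truth for both survey schemas.

``simulate_population`` emulates the long-term transect series: a latent
size-structured population driven by year-varying survival and
recruitment, observed through a size-specific detection probability that
takes a step increase at the outbreak year (the detection step is the
behavioural shift being emulated: urchins emerging from crevices become
countable).  ``simulate_mosaic`` emulates the patch survey: a mosaic of
forest/barren sites whose year-to-year state transitions are logistic in
the log density of exposed urchins, with distinct forward and reverse
thresholds (hysteresis).

Both generators are pure functions of their scenario (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidParamsError
from .growth import build_growth_matrix
from .patchstate import COVER_GROUPS, PatchSurvey
from .popmodel import LatentPopulation, ModelConfig, SizeFrequency, _forward_latent

__all__ = [
    "PopScenario",
    "MosaicScenario",
    "SimulatedPopulation",
    "SimulatedMosaic",
    "step_path",
    "simulate_population",
    "simulate_mosaic",
]


def step_path(years, pre_value: float, post_value: float, first_post_year: int) -> np.ndarray:
    """Piecewise-constant annual path with a step at ``first_post_year``."""
    years = np.asarray(years)
    return np.where(years >= first_post_year, post_value, pre_value).astype(float)


# ---------------------------------------------------------------------------
# population scenario


@dataclass
class PopScenario:
    """Truth for the transect-survey generator.

    Defaults emulate the study conditions: 23 survey years (1999–2021), a
    10-fold step in detection probability and a 2-fold step in
    recruitment when the post-outbreak period starts in 2014, flat
    survival, six transects per year, negative-binomial counts.
    """

    seed: int
    years: np.ndarray = field(default_factory=lambda: np.arange(1999, 2022))
    config: ModelConfig = field(default_factory=ModelConfig)
    survival: float | np.ndarray = 0.85
    recruitment: float | np.ndarray | None = None  # default: step 15 -> 30 in 2014
    detection: float | np.ndarray | None = None  # default: step 0.05 -> 0.5 in 2014
    detect_size_logit_slope: float = 0.0  # size trend in detection (per class index)
    n_transects: int = 6
    overdispersion: float = 10.0
    spinup_years: int = 50  # pre-study burn-in to set the initial latent state
    init_N0: np.ndarray | None = None  # overrides the spinup when given

    def _path(self, x, default_pre, default_post) -> np.ndarray:
        T = len(self.years)
        if x is None:
            return step_path(self.years, default_pre, default_post, self.config.break_year + 1)
        x = np.asarray(x, dtype=float)
        if x.ndim == 0:
            return np.full(T, float(x))
        if x.shape[-1] != T:
            raise InvalidParamsError("path length must match the number of years")
        return x

    def survival_path(self) -> np.ndarray:
        p = self._path(self.survival, None, None)
        if np.any((p <= 0) | (p >= 1)):
            raise InvalidParamsError("survival path must lie in (0,1)")
        return p

    def recruitment_path(self) -> np.ndarray:
        p = self._path(self.recruitment, 15.0, 30.0)
        if np.any(p < 0):
            raise InvalidParamsError("recruitment path must be non-negative")
        return p

    def detection_matrix(self) -> np.ndarray:
        """(S, T) detection probabilities."""
        S = self.config.n_classes
        d = self.detection
        if d is not None and np.ndim(d) == 2:
            d = np.asarray(d, dtype=float)
            if d.shape != (S, len(self.years)):
                raise InvalidParamsError("detection matrix must be S x T")
            mat = d
        else:
            path = self._path(d, 0.05, 0.5)
            k = np.arange(S) - (S - 1) / 2.0
            logits = (
                np.log(path / (1 - path))[None, :]
                + self.detect_size_logit_slope * k[:, None]
            )
            mat = expit(logits)
        if np.any((mat <= 0) | (mat >= 1)):
            raise InvalidParamsError("detection probabilities must lie in (0,1)")
        return mat


@dataclass
class SimulatedPopulation:
    latent: LatentPopulation
    observations: list  # of SizeFrequency
    detection: np.ndarray  # (S, T) truth
    survival: np.ndarray  # (T,) truth
    recruitment: np.ndarray  # (T,) truth
    scenario: PopScenario


def simulate_population(sc: PopScenario) -> SimulatedPopulation:
    """Simulate the latent population and its observed transect counts."""
    cfg = sc.config
    G = build_growth_matrix(cfg.growth, cfg.bin_edges).probs
    S, T = cfg.n_classes, len(sc.years)
    surv = sc.survival_path()
    rec = sc.recruitment_path()
    detect = sc.detection_matrix()

    if sc.init_N0 is not None:
        N0 = np.asarray(sc.init_N0, dtype=float)
    else:  # burn in at first-year rates to a stable size structure
        N0 = np.zeros(S)
        for _ in range(sc.spinup_years):
            N0 = surv[0] * (N0 @ G)
            N0[0] += rec[0]
    N = _forward_latent(N0, G, surv, rec)
    lam = detect * N

    rng = np.random.default_rng(sc.seed)
    obs = []
    for t, year in enumerate(sc.years):
        mu = np.tile(lam[:, t], (sc.n_transects, 1))
        if cfg.family == "poisson":
            y = rng.poisson(mu)
        else:
            phi = sc.overdispersion
            y = rng.negative_binomial(phi, phi / (phi + np.maximum(mu, 1e-300)))
        for i in range(sc.n_transects):
            obs.append(
                SizeFrequency(
                    year=int(year), site_id="synth", transect_id=f"T{i+1}", counts=y[i]
                )
            )
    return SimulatedPopulation(
        latent=LatentPopulation(N=N, years=sc.years),
        observations=obs,
        detection=detect,
        survival=surv,
        recruitment=rec,
        scenario=sc,
    )


# ---------------------------------------------------------------------------
# patch-mosaic scenario


@dataclass
class MosaicScenario:
    """Truth for the patch-survey generator.

    Transition probabilities are logistic in ln(exposed density): a
    forest forward-shifts with probability expit(slope_f * (ln d - ln
    d50_f)) and a barren reverse-shifts with probability expit(slope_r *
    (ln d - ln d50_r)); the default 50% thresholds are 2.71 (forward) and
    0.03 (reverse) urchins per m^2, a strongly hysteretic pair.
    State-conditional exposed densities are lognormal and heavy-tailed in
    barrens; cover fractions are multinomial point counts from
    state-conditional Dirichlet compositions (four indicator groups plus
    bare substrate).
    """

    seed: int
    n_sites: int = 300
    years: tuple = (2017, 2018, 2019)
    init_barren_frac: float = 0.4
    forward_threshold: float = 2.71  # exposed urchins / m^2
    reverse_threshold: float = 0.03
    forward_slope: float = 2.2  # on ln density; > 0
    reverse_slope: float = -1.3  # < 0: sparse barrens recover
    hysteresis: bool = True
    # state-conditional lognormal (mean of ln, sd of ln) for densities
    exposed_lognorm: dict = field(
        default_factory=lambda: {
            "forest": (np.log(0.5), 1.5),
            "barren": (np.log(1.5), 2.5),
        }
    )
    concealed_lognorm: dict = field(
        default_factory=lambda: {
            "forest": (np.log(2.5), 0.6),
            "barren": (np.log(0.8), 0.8),
        }
    )
    # Dirichlet over (articulated, encrusting, brown, foliose, bare)
    cover_alpha: dict = field(
        default_factory=lambda: {
            "forest": (2.0, 2.0, 6.0, 4.0, 2.0),
            "barren": (1.0, 8.0, 0.5, 0.5, 6.0),
        }
    )
    label_noise: float = 0.02  # field-impression mislabel probability
    n_quadrats: int = 16
    points_per_quadrat: int = 16
    depth_range: tuple = (5.0, 20.0)
    density_floor: float = 0.01  # ln argument floor for the transition rule

    def __post_init__(self):
        if self.hysteresis and not self.forward_threshold > self.reverse_threshold:
            raise InvalidParamsError(
                "hysteresis requires forward threshold > reverse threshold"
            )
        if self.forward_slope <= 0 or self.reverse_slope >= 0:
            raise InvalidParamsError(
                "forward slope must be > 0 and reverse slope < 0"
            )

    def transition_prob(self, state: str, exposed_density: float) -> float:
        """True probability the patch switches state next year."""
        d = max(exposed_density, self.density_floor)
        if state == "forest":
            return float(expit(self.forward_slope * (np.log(d) - np.log(self.forward_threshold))))
        return float(expit(self.reverse_slope * (np.log(d) - np.log(self.reverse_threshold))))


@dataclass
class SimulatedMosaic:
    surveys: list  # of PatchSurvey (site-level quadrat means)
    quadrats: pd.DataFrame  # quadrat-level rows in the CSV schema
    states: pd.DataFrame  # site, year, true_state
    scenario: MosaicScenario


def simulate_mosaic(sc: MosaicScenario) -> SimulatedMosaic:
    """Simulate the patch mosaic with true states and transitions."""
    rng = np.random.default_rng(sc.seed)
    n = sc.n_sites
    state = np.where(rng.random(n) < sc.init_barren_frac, "barren", "forest")
    depth = rng.uniform(*sc.depth_range, size=n)

    surveys, qrows, srows = [], [], []
    for year in sc.years:
        next_state = state.copy()
        for i in range(n):
            st = state[i]
            mu_e, sd_e = sc.exposed_lognorm[st]
            mu_c, sd_c = sc.concealed_lognorm[st]
            site_exposed = float(np.exp(rng.normal(mu_e, sd_e)))
            site_concealed = float(np.exp(rng.normal(mu_c, sd_c)))
            cover = rng.dirichlet(sc.cover_alpha[st])

            eq = rng.poisson(site_exposed, sc.n_quadrats)
            cq = rng.poisson(site_concealed, sc.n_quadrats)
            pts = rng.multinomial(sc.points_per_quadrat, cover, size=sc.n_quadrats)
            covq = pts[:, :4] / sc.points_per_quadrat

            field_state = st
            if rng.random() < sc.label_noise:
                field_state = "barren" if st == "forest" else "forest"

            site_id = f"S{i+1:03d}"
            for q in range(sc.n_quadrats):
                qrows.append(
                    {
                        "site": site_id,
                        "year": year,
                        "quadrat": q + 1,
                        "exposed_count": int(eq[q]),
                        "concealed_count": int(cq[q]),
                        **{
                            f"cover_{g}": covq[q, j]
                            for j, g in enumerate(COVER_GROUPS)
                        },
                        "field_state": field_state,
                        "depth_m": depth[i],
                    }
                )
            exp_mean = eq.mean()
            con_mean = cq.mean()
            surveys.append(
                PatchSurvey(
                    site_id=site_id,
                    year=int(year),
                    exposed_density=float(exp_mean),
                    concealed_density=float(con_mean),
                    cover={g: float(covq[:, j].mean()) for j, g in enumerate(COVER_GROUPS)},
                    field_state=field_state,
                    depth_m=float(depth[i]),
                )
            )
            srows.append({"site": site_id, "year": year, "true_state": st})

            # state transition into the following year, from realised density
            p = sc.transition_prob(st, float(exp_mean))
            if rng.random() < p:
                next_state[i] = "barren" if st == "forest" else "forest"
        state = next_state

    return SimulatedMosaic(
        surveys=surveys,
        quadrats=pd.DataFrame(qrows),
        states=pd.DataFrame(srows),
        scenario=sc,
    )
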