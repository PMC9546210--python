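"""Patch-state classification and transition dynamics.

A reef patch (survey site) is either a kelp *forest* or an urchin
*barren*.  Site state is classified with a two-class linear discriminant
(Gaussian classes, pooled covariance) trained on urchin behaviour
(exposed and concealed densities), total density and the cover of four
indicator algal groups.  Year-to-year transitions between states are
modelled with logistic regression on the natural-log density of exposed
urchins, concealed density and starting state, with AICc model
selection; the exposed density at which the transition probability
crosses 50% gives the forward (forest->barren) and reverse
(barren->forest) thresholds whose separation measures hysteresis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DataError, DimensionError, InvalidParamsError

__all__ = [
    "PatchSurvey",
    "StateModel",
    "TransitionRecord",
    "TransitionTable",
    "LogisticFit",
    "ThresholdResult",
    "COVER_GROUPS",
    "FEATURE_COLUMNS",
    "patch_features",
    "lda_train",
    "lda_classify",
    "classify_surveys",
    "transition_table",
    "logistic_fit",
    "select_model",
    "threshold_50",
]

STATES = ("forest", "barren")
COVER_GROUPS = ("articulated_coralline", "encrusting_coralline_red", "brown", "foliose_red")
# total density is omitted: it is the sum of the two behaviour densities,
# which would make the pooled covariance exactly singular
FEATURE_COLUMNS = (
    "exposed_density",
    "concealed_density",
) + tuple(f"cover_{g}" for g in COVER_GROUPS)

#: model terms understood by logistic_fit; 'state' is 1 for a barren start
TERMS = ("log_exposed", "concealed", "state", "log_exposed:state", "concealed:state")


@dataclass(frozen=True)
class PatchSurvey:
    """One site-year of the patch survey (quadrat means)."""

    site_id: str
    year: int
    exposed_density: float  # exposed urchins per m^2
    concealed_density: float
    cover: dict  # fraction per COVER_GROUPS entry
    field_state: str  # diver impression: forest / barren
    depth_m: float
    total_density: float | None = None

    def __post_init__(self):
        if self.total_density is None:
            object.__setattr__(
                self, "total_density", self.exposed_density + self.concealed_density
            )
        if self.exposed_density < 0 or self.concealed_density < 0:
            raise DataError("densities must be non-negative")
        if self.exposed_density > self.total_density + 1e-9:
            raise DataError("exposed density cannot exceed total density")
        for g in COVER_GROUPS:
            f = self.cover.get(g)
            if f is None or not (0.0 <= f <= 1.0):
                raise DataError(f"cover fraction '{g}' must be in [0, 1]")
        if self.field_state not in STATES:
            raise DataError(f"field_state must be one of {STATES}")


def patch_features(surveys: Sequence[PatchSurvey]) -> np.ndarray:
    """Feature matrix in FEATURE_COLUMNS order."""
    rows = [
        [s.exposed_density, s.concealed_density] + [s.cover[g] for g in COVER_GROUPS]
        for s in surveys
    ]
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# linear discriminant classifier


@dataclass
class StateModel:
    """Two-class Gaussian discriminant with pooled within-class covariance."""

    class_means: np.ndarray  # (2, d), rows ordered as STATES
    pooled_cov: np.ndarray  # (d, d)
    priors: np.ndarray  # (2,)
    misclassified: int
    entropy_r2: float
    feature_names: tuple = FEATURE_COLUMNS

    def _discriminants(self, X: np.ndarray) -> np.ndarray:
        """delta_c(x) = x' S^-1 mu_c - 0.5 mu_c' S^-1 mu_c + log pi_c."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.class_means.shape[1]:
            raise DimensionError(
                f"expected {self.class_means.shape[1]} features, got {X.shape[1]}"
            )
        A = np.linalg.solve(self.pooled_cov, self.class_means.T)  # (d, 2)
        const = -0.5 * np.einsum("cd,dc->c", self.class_means, A) + np.log(self.priors)
        return X @ A + const


def lda_train(
    features: np.ndarray,
    labels: Sequence[str],
    priors: np.ndarray | None = None,
    feature_names: tuple = FEATURE_COLUMNS,
) -> StateModel:
    """Train the patch-state discriminant.

    Class priors default to the empirical class frequencies.  A singular
    pooled covariance is ridge-regularised (small diagonal inflation)
    with a warning.  Training diagnostics: resubstitution misclassified
    count and McFadden-style entropy R^2 of the label likelihood.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("features must be n x d with one label per row")
    if not np.all(np.isfinite(X)):
        raise DataError("features must be finite")
    masks = [y == s for s in STATES]
    ns = np.array([m.sum() for m in masks])
    if np.any(ns < 2):
        raise DataError("need at least 2 samples per class")
    n, d = X.shape
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    pooled = sum(
        (X[m] - means[i]).T @ (X[m] - means[i]) for i, m in enumerate(masks)
    ) / (n - 2)
    eig_floor = 1e-10 * max(np.trace(pooled) / d, 1e-30)
    if np.linalg.eigvalsh(pooled)[0] < eig_floor:
        warnings.warn("singular pooled covariance; applying ridge regularisation")
        pooled = pooled + np.eye(d) * max(1e-8 * np.trace(pooled) / d, 1e-12)
    pri = ns / n if priors is None else np.asarray(priors, dtype=float)

    model = StateModel(
        class_means=means,
        pooled_cov=pooled,
        priors=pri,
        misclassified=0,
        entropy_r2=np.nan,
        feature_names=tuple(feature_names),
    )
    pred, prob = lda_classify(model, X)
    model.misclassified = int(np.sum(pred != y))
    # entropy (McFadden) R^2 of the class labels
    idx = (y == STATES[1]).astype(int)
    p_true = np.clip(prob[np.arange(n), idx], 1e-300, 1.0)
    ll = np.log(p_true).sum()
    ll0 = np.sum(ns * np.log(ns / n))
    model.entropy_r2 = float(1.0 - ll / ll0) if ll0 != 0 else 1.0
    return model


def lda_classify(model: StateModel, features: np.ndarray):
    """Predicted state and class posterior probabilities.

    Returns (labels (n,), probs (n, 2) ordered as STATES).  An exact
    posterior tie classifies as forest.
    """
    delta = model._discriminants(features)
    delta = delta - delta.max(axis=1, keepdims=True)
    probs = np.exp(delta)
    probs /= probs.sum(axis=1, keepdims=True)
    labels = np.where(probs[:, 1] > probs[:, 0], STATES[1], STATES[0])
    return labels, probs


def classify_surveys(model: StateModel, surveys: Sequence[PatchSurvey]) -> pd.DataFrame:
    """Classify a survey collection; one row per site-year."""
    X = patch_features(surveys)
    labels, probs = lda_classify(model, X)
    return pd.DataFrame(
        {
            "site": [s.site_id for s in surveys],
            "year": [s.year for s in surveys],
            "state": labels,
            "prob_barren": probs[:, 1],
            "field_state": [s.field_state for s in surveys],
            "exposed_density": [s.exposed_density for s in surveys],
            "concealed_density": [s.concealed_density for s in surveys],
        }
    )


# ---------------------------------------------------------------------------
# transitions


@dataclass(frozen=True)
class TransitionRecord:
    """One site observed in consecutive years."""

    site_id: str
    start_year: int
    start_state: str
    end_state: str
    exposed_density: float  # starting-year value
    concealed_density: float

    @property
    def outcome(self) -> int:
        return int(self.start_state != self.end_state)


@dataclass
class TransitionTable:
    """Paired consecutive-year site records and their transition counts."""

    records: list  # of TransitionRecord
    counts: dict  # persisted / forward / reverse
    log_offset: float  # c in ln(exposed + c)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site": [r.site_id for r in self.records],
                "start_year": [r.start_year for r in self.records],
                "start_state": [r.start_state for r in self.records],
                "end_state": [r.end_state for r in self.records],
                "exposed_density": [r.exposed_density for r in self.records],
                "concealed_density": [r.concealed_density for r in self.records],
                "outcome": [r.outcome for r in self.records],
            }
        )
        df["log_exposed"] = np.log(df["exposed_density"] + self.log_offset)
        df["state"] = (df["start_state"] == "barren").astype(float)
        return df


def transition_table(
    classified: pd.DataFrame, state_col: str = "state", log_offset: float | None = None
) -> TransitionTable:
    """Pair site observations in consecutive years and count transitions.

    ``classified`` needs columns site, year, exposed_density,
    concealed_density and the state column.  Only sites surveyed in
    sequential years contribute; each pair yields exactly one record.
    ``log_offset`` defaults to half the minimum nonzero starting exposed
    density (for ln(0) handling downstream).
    """
    df = classified
    for col in ("site", "year", "exposed_density", "concealed_density", state_col):
        if col not in df.columns:
            raise DataError(f"missing column '{col}'")
    if df.duplicated(subset=["site", "year"]).any():
        raise DataError("duplicate site-year rows")
    records = []
    for site, grp in df.groupby("site", sort=True):
        grp = grp.sort_values("year")
        by_year = {int(r.year): r for r in grp.itertuples()}
        for y in sorted(by_year):
            if y + 1 in by_year:
                a, b = by_year[y], by_year[y + 1]
                records.append(
                    TransitionRecord(
                        site_id=str(site),
                        start_year=y,
                        start_state=getattr(a, state_col),
                        end_state=getattr(b, state_col),
                        exposed_density=float(a.exposed_density),
                        concealed_density=float(a.concealed_density),
                    )
                )
    counts = {"persisted": 0, "forward": 0, "reverse": 0}
    for r in records:
        if r.start_state == r.end_state:
            counts["persisted"] += 1
        elif r.start_state == "forest":
            counts["forward"] += 1
        else:
            counts["reverse"] += 1
    if log_offset is None:
        nz = [r.exposed_density for r in records if r.exposed_density > 0]
        log_offset = 0.5 * min(nz) if nz else 1e-3
    return TransitionTable(records=records, counts=counts, log_offset=log_offset)


# ---------------------------------------------------------------------------
# logistic transition model


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression of state change on predictors."""

    terms: tuple
    coef: dict  # term -> coefficient, including 'intercept'
    loglik: float
    aicc: float
    mcfadden_r2: float
    n: int
    converged: bool
    separation: bool
    log_offset: float


_TERM_COLUMNS = {"log_exposed": "log_exposed", "concealed": "concealed_density", "state": "state"}


def _design(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]

    def col(name):
        return df[_TERM_COLUMNS[name]].to_numpy(dtype=float)

    for t in terms:
        if t not in TERMS:
            raise InvalidParamsError(f"unknown term {t!r}; choose from {TERMS}")
        if ":" in t:
            a, b = t.split(":")
            cols.append(col(a) * col(b))
        else:
            cols.append(col(t))
    return np.column_stack(cols)


def logistic_fit(
    records: TransitionTable | pd.DataFrame, terms: Sequence[str]
) -> LogisticFit:
    """Fit transition probability by IRLS.

    The response is 1 for a state change in the following year, 0 for
    persistence.  Complete separation is flagged (diverging
    coefficients), not raised.
    """
    offset = records.log_offset if isinstance(records, TransitionTable) else 0.0
    df = records.frame() if isinstance(records, TransitionTable) else records
    y = df["outcome"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("need at least one transition and one persistence")
    X = _design(df, terms)
    n, p = X.shape

    beta = np.zeros(p)
    converged = False
    for _ in range(200):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    separation = (not converged) or bool(np.max(np.abs(beta)) > 25)
    if separation:
        warnings.warn(
            "possible complete separation: coefficients diverging", RuntimeWarning
        )

    eta = np.clip(X @ beta, -700, 700)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    pbar = y.mean()
    ll0 = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    aicc = -2 * ll + 2 * p + 2 * p * (p + 1) / max(n - p - 1, 1)
    names = ("intercept",) + tuple(terms)
    return LogisticFit(
        terms=tuple(terms),
        coef=dict(zip(names, beta.tolist())),
        loglik=ll,
        aicc=float(aicc),
        mcfadden_r2=float(1.0 - ll / ll0) if ll0 != 0 else np.nan,
        n=n,
        converged=converged,
        separation=separation,
        log_offset=offset,
    )


def select_model(
    candidates: Sequence[Sequence[str]], records: TransitionTable | pd.DataFrame
) -> tuple[LogisticFit, pd.DataFrame]:
    """AICc model selection over candidate term sets.

    Returns the winning fit (first listed on an exact tie) and the
    Delta-AICc table.
    """
    if len(candidates) < 2:
        raise InvalidParamsError("need at least 2 candidate formulas")
    fits = [logistic_fit(records, terms) for terms in candidates]
    aiccs = np.array([f.aicc for f in fits])
    best = int(np.argmin(aiccs))  # argmin keeps the first on ties
    table = pd.DataFrame(
        {
            "formula": [" + ".join(t) if t else "intercept-only" for t in candidates],
            "n_params": [len(f.coef) for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": aiccs,
            "dAICc": aiccs - aiccs[best],
            "mcfadden_r2": [f.mcfadden_r2 for f in fits],
        }
    )
    return fits[best], table


@dataclass(frozen=True)
class ThresholdResult:
    """Exposed density at which the transition probability is 50%."""

    density: float  # urchins per m^2
    start_state: str
    extrapolated: bool


def threshold_50(
    fit: LogisticFit,
    start_state: str,
    records: TransitionTable | pd.DataFrame | None = None,
) -> ThresholdResult:
    """Solve for the 50% transition threshold for a given starting state.

    Other predictors are held at their state-conditional means (computed
    from ``records`` when given, else zero); the linear predictor is
    solved for zero on the ln(exposed + c) scale and back-transformed.
    A threshold outside the observed exposed-density range for that
    state is flagged as extrapolated.
    """
    if start_state not in STATES:
        raise InvalidParamsError(f"start_state must be one of {STATES}")
    if "log_exposed" not in fit.terms:
        raise InvalidParamsError("fitted model must include log exposed density")
    s = 1.0 if start_state == "barren" else 0.0
    slope = fit.coef["log_exposed"] + s * fit.coef.get("log_exposed:state", 0.0)
    if slope == 0:
        raise InvalidParamsError(f"zero slope on log exposed density for {start_state}")

    df = None
    if records is not None:
        df = records.frame() if isinstance(records, TransitionTable) else records
        sub = df[df["start_state"] == start_state] if "start_state" in df.columns else df
    conc = float(sub["concealed_density"].mean()) if df is not None and len(sub) else 0.0

    eta0 = fit.coef["intercept"] + s * fit.coef.get("state", 0.0)
    eta0 += (fit.coef.get("concealed", 0.0) + s * fit.coef.get("concealed:state", 0.0)) * conc
    log_d = -eta0 / slope
    density = float(np.exp(log_d) - fit.log_offset)

    extrapolated = False
    if df is not None and len(sub):
        lo, hi = sub["exposed_density"].min(), sub["exposed_density"].max()
        extrapolated = not (lo <= density <= hi)
    return ThresholdResult(density=density, start_state=start_state, extrapolated=extrapolated)
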