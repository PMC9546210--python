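"""CSV readers/writers, run configuration and the umbrella pipeline.

Two tabular schemas are supported (comma-separated, UTF-8, '.' decimal,
mandatory header):

* transect counts (long): year, site, transect, size_class_cm, count
  (+ optional zone_depth_m); size_class_cm is the lower edge of the 1-cm
  class;
* patch quadrats: site, year, quadrat, exposed_count, concealed_count,
  cover_<group> for the four indicator algal groups, field_state,
  depth_m.  Quadrats are 1 m^2, so counts are densities; the reader
  aggregates to site-year means.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .changepoint import fit_segmented, select_n_breaks
from .errors import ConfigError, DataError, PipelineError, SchemaError
from .patchstate import (
    COVER_GROUPS,
    PatchSurvey,
    classify_surveys,
    lda_train,
    logistic_fit,
    patch_features,
    select_model,
    threshold_50,
    transition_table,
)
from .popmodel import (
    ModelConfig,
    PosteriorSamples,
    SizeFrequency,
    default_bin_edges,
    fit_mcmc,
    fold_change_summary,
    hindcast_density,
)
from .sensitivity import partition_increase
from .synth import MosaicScenario, PopScenario, simulate_mosaic, simulate_population

__all__ = [
    "read_transect_csv",
    "write_transect_csv",
    "read_patch_csv",
    "write_quadrat_csv",
    "summarize_posterior",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("kelpatch")

TRANSECT_COLUMNS = ("year", "site", "transect", "size_class_cm", "count")
PATCH_COLUMNS = (
    "site",
    "year",
    "quadrat",
    "exposed_count",
    "concealed_count",
) + tuple(f"cover_{g}" for g in COVER_GROUPS) + ("field_state", "depth_m")


def _check_columns(df: pd.DataFrame, required, optional=()):
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")
    unknown = set(df.columns) - set(required) - set(optional)
    if unknown:
        warnings.warn(f"ignoring unknown columns: {sorted(unknown)}")


def read_transect_csv(path, bin_edges: np.ndarray | None = None) -> list[SizeFrequency]:
    """Read long-format transect counts into a SizeFrequency collection."""
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    df = pd.read_csv(path)
    if df.empty:
        _check_columns(df, TRANSECT_COLUMNS, optional=("zone_depth_m",))
        return []
    _check_columns(df, TRANSECT_COLUMNS, optional=("zone_depth_m",))
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise DataError(f"negative count at row {int(bad[0]) + 2}")  # 1-based + header
    lower = edges[:-1]
    class_index = {float(e): k for k, e in enumerate(lower)}
    unknown_sizes = set(df["size_class_cm"].astype(float)) - set(class_index)
    if unknown_sizes:
        raise DataError(
            f"size_class_cm values {sorted(unknown_sizes)} do not match the bin edges"
        )
    out = []
    for (year, site, transect), grp in df.groupby(
        ["year", "site", "transect"], sort=True
    ):
        counts = np.zeros(len(lower), dtype=np.int64)
        for sz, c in zip(grp["size_class_cm"].astype(float), grp["count"]):
            counts[class_index[sz]] += int(c)
        out.append(
            SizeFrequency(
                year=int(year), site_id=str(site), transect_id=str(transect), counts=counts
            )
        )
    return out


def write_transect_csv(
    data: Sequence[SizeFrequency], path, bin_edges: np.ndarray | None = None
) -> None:
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    lower = edges[:-1]
    rows = [
        {
            "year": rec.year,
            "site": rec.site_id,
            "transect": rec.transect_id,
            "size_class_cm": lower[k],
            "count": int(rec.counts[k]),
        }
        for rec in data
        for k in range(len(lower))
    ]
    pd.DataFrame(rows, columns=list(TRANSECT_COLUMNS)).to_csv(path, index=False)


def read_patch_csv(path) -> list[PatchSurvey]:
    """Read quadrat-level patch surveys, aggregated to site-year means."""
    df = pd.read_csv(path)
    _check_columns(df, PATCH_COLUMNS)
    if df.empty:
        return []
    for col in ("exposed_count", "concealed_count"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise DataError(f"negative {col} at row {int(bad[0]) + 2}")
    for g in COVER_GROUPS:
        col = f"cover_{g}"
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise DataError(f"cover fraction outside [0,1] at row {int(bad[0]) + 2}")
    out = []
    for (site, year), grp in df.groupby(["site", "year"], sort=True):
        states = grp["field_state"].unique()
        if len(states) > 1:
            raise DataError(f"conflicting field_state for site {site} year {year}")
        out.append(
            PatchSurvey(
                site_id=str(site),
                year=int(year),
                exposed_density=float(grp["exposed_count"].mean()),
                concealed_density=float(grp["concealed_count"].mean()),
                cover={g: float(grp[f"cover_{g}"].mean()) for g in COVER_GROUPS},
                field_state=str(states[0]),
                depth_m=float(grp["depth_m"].mean()),
            )
        )
    return out


def write_quadrat_csv(quadrats: pd.DataFrame, path) -> None:
    quadrats.to_csv(path, index=False)


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summary table: parameter, mean, sd, q5, q50, q95, rhat."""
    if samples.theta is None:
        raise DataError("samples carry no raw parameter draws")
    flat = samples.theta.reshape(-1, samples.theta.shape[-1])
    q5, q50, q95 = np.percentile(flat, [5, 50, 95], axis=0)
    return pd.DataFrame(
        {
            "parameter": samples.param_names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q5": q5,
            "q50": q50,
            "q95": q95,
            "rhat": [samples.rhat[n] for n in samples.param_names],
        }
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline."""

    seed: int
    outdir: Path
    transect_csv: Path | None = None  # None -> simulate the default scenario
    patch_csv: Path | None = None
    break_year: int = 2013
    chains: int = 2
    draws: int = 800
    warmup: int = 800
    thin: int = 1
    max_breaks: int = 3
    model: ModelConfig = field(default_factory=ModelConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ConfigError("config must set a seed")
    fit = raw.get("fit", {})
    cfg = RunConfig(
        seed=int(raw["seed"]),
        outdir=Path(raw.get("outdir", "kelpatch_out")),
        transect_csv=Path(raw["transect_csv"]) if raw.get("transect_csv") else None,
        patch_csv=Path(raw["patch_csv"]) if raw.get("patch_csv") else None,
        break_year=int(raw.get("break_year", 2013)),
        chains=int(fit.get("chains", 2)),
        draws=int(fit.get("draws", 800)),
        warmup=int(fit.get("warmup", 800)),
        thin=int(fit.get("thin", 1)),
        max_breaks=int(raw.get("max_breaks", 3)),
    )
    for p in (cfg.transect_csv, cfg.patch_csv):
        if p is not None and not p.exists():
            raise ConfigError(f"input path does not exist: {p}")
    return cfg


_CANDIDATE_FORMULAS = (
    ("log_exposed", "state"),
    ("concealed", "state"),
    ("log_exposed", "concealed", "state"),
    ("log_exposed", "state", "log_exposed:state"),
    ("state",),
)


def run_pipeline(config: RunConfig) -> dict:
    """Run fit -> partition -> changepoint -> classify -> transitions -> thresholds.

    Writes all output CSVs plus a run log under ``config.outdir`` and
    returns a dict of output paths.  A stage failure raises
    PipelineError naming the stage; outputs written so far are kept.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    import kelpatch

    log.info("kelpatch %s | numpy %s | seed %s", kelpatch.__version__, np.__version__, config.seed)

    def stage(name):
        log.info("stage %s", name)
        return time.time()

    try:
        t0 = stage("load-transects")
        if config.transect_csv is not None:
            data = read_transect_csv(config.transect_csv)
        else:
            sim = simulate_population(PopScenario(seed=config.seed))
            data = sim.observations
            paths["transects"] = out / "simulated_transects.csv"
            write_transect_csv(data, paths["transects"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load-transects", str(e)) from e

    try:
        t0 = stage("fit")
        samples = fit_mcmc(
            data,
            config.model,
            seed=config.seed,
            chains=config.chains,
            draws=config.draws,
            warmup=config.warmup,
            thin=config.thin,
        )
        paths["posterior_summary"] = out / "posterior_summary.csv"
        summarize_posterior(samples).to_csv(paths["posterior_summary"], index=False)
        paths["hindcast"] = out / "hindcast.csv"
        hindcast_density(samples).to_csv(paths["hindcast"], index=False)
        paths["fold_changes"] = out / "fold_changes.csv"
        fold_change_summary(samples, config.break_year).summary().to_csv(
            paths["fold_changes"], index=False
        )
        log.info("fit done in %.1fs (converged=%s)", time.time() - t0, samples.converged)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", str(e)) from e

    try:
        stage("partition")
        contrib = partition_increase(samples, config.break_year)
        paths["contributions"] = out / "contributions.csv"
        contrib.summary().to_csv(paths["contributions"], index=False)
        paths["contribution_draws"] = out / "contribution_draws.csv"
        contrib.draws_frame().to_csv(paths["contribution_draws"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("partition", str(e)) from e

    try:
        stage("changepoint")
        by_year: dict[int, list] = {}
        for rec in data:
            by_year.setdefault(rec.year, []).append(rec.counts.sum())
        years = np.array(sorted(by_year))
        dens = np.array([np.mean(by_year[y]) for y in years])
        nb = select_n_breaks(years, dens, config.max_breaks)
        fit = fit_segmented(years, dens, nb)
        paths["changepoint"] = out / "changepoint.csv"
        pd.DataFrame(
            {
                "breakpoint": list(fit.breakpoints) or [np.nan],
                "n_breaks": nb,
                "rss": fit.rss,
                "bic": fit.ic,
            }
        ).to_csv(paths["changepoint"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("changepoint", str(e)) from e

    try:
        stage("classify")
        if config.patch_csv is not None:
            surveys = read_patch_csv(config.patch_csv)
        else:
            mosaic = simulate_mosaic(MosaicScenario(seed=config.seed + 1))
            surveys = mosaic.surveys
            paths["quadrats"] = out / "simulated_quadrats.csv"
            write_quadrat_csv(mosaic.quadrats, paths["quadrats"])
        model = lda_train(
            patch_features(surveys), [s.field_state for s in surveys]
        )
        classified = classify_surveys(model, surveys)
        paths["classified"] = out / "classified.csv"
        classified.to_csv(paths["classified"], index=False)
        log.info(
            "LDA: %d misclassified of %d, entropy R2 %.3f",
            model.misclassified,
            len(surveys),
            model.entropy_r2,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", str(e)) from e

    try:
        stage("transitions")
        table = transition_table(classified)
        paths["transitions"] = out / "transitions.csv"
        table.frame().to_csv(paths["transitions"], index=False)
        paths["transition_counts"] = out / "transition_counts.csv"
        pd.DataFrame([table.counts]).to_csv(paths["transition_counts"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("transitions", str(e)) from e

    try:
        stage("thresholds")
        best, sel = select_model(_CANDIDATE_FORMULAS, table)
        paths["model_selection"] = out / "model_selection.csv"
        sel.to_csv(paths["model_selection"], index=False)
        if "log_exposed" not in best.terms:  # thresholds need the density term
            best = logistic_fit(table, ("log_exposed", "state", "log_exposed:state"))
        rows = []
        for state in ("forest", "barren"):
            th = threshold_50(best, state, table)
            rows.append(
                {
                    "start_state": state,
                    "threshold_per_m2": th.density,
                    "extrapolated": th.extrapolated,
                }
            )
        paths["thresholds"] = out / "thresholds.csv"
        pd.DataFrame(rows).to_csv(paths["thresholds"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("thresholds", str(e)) from e
    finally:
        log.removeHandler(handler)
        handler.close()

    return paths
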