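"""MCMC fitting: determinism, recovery, diagnostics, posterior summaries."""

import numpy as np
import pytest

import kelpatch as kp
from kelpatch.errors import DataError, InvalidParamsError
from kelpatch.popmodel import (
    ModelConfig,
    PosteriorSamples,
    fold_change_summary,
    hindcast_density,
    posterior_predictive_check,
)


def small_scenario(seed=5):
    return kp.PopScenario(seed=seed, years=np.arange(2005, 2013), n_transects=3)


def test_same_seed_gives_identical_draws():
    sim = kp.simulate_population(small_scenario())
    kw = dict(chains=2, draws=60, warmup=120)
    a = kp.fit_mcmc(sim.observations, seed=42, **kw)
    b = kp.fit_mcmc(sim.observations, seed=42, **kw)
    assert np.array_equal(a.theta, b.theta)
    c = kp.fit_mcmc(sim.observations, seed=43, **kw)
    assert not np.array_equal(a.theta, c.theta)


def test_input_validation():
    sim = kp.simulate_population(small_scenario())
    with pytest.raises(DataError):
        kp.fit_mcmc([], seed=1)
    with pytest.raises(InvalidParamsError):
        kp.fit_mcmc(sim.observations, seed=1, chains=1)


def test_rhat_reported_and_convergence_rule(pop_fit):
    assert set(pop_fit.rhat) == set(pop_fit.param_names)
    vals = [v for v in pop_fit.rhat.values() if np.isfinite(v)]
    assert vals and all(v > 0.8 for v in vals)
    assert pop_fit.converged == (max(vals) < 1.05)


def test_detection_fold_change_interval_contains_truth(pop_fit):
    """A x10 detection step in the generating truth is recovered by the
    posterior 90% credible interval of the detection fold change."""
    fc = fold_change_summary(pop_fit, 2013)
    lo, hi = fc.interval("detection")
    assert lo <= 10.0 <= hi
    lo, hi = fc.interval("survival")
    assert lo <= 1.0 <= hi or abs(np.mean(fc.draws["survival"]) - 1.0) < 0.1


def test_uninformed_year_effect_shrinks_to_prior(pop_fit):
    """The first-year survival deviation has no transition to inform it, so
    its (non-centred) posterior should match the standard-normal prior."""
    i = pop_fit.param_names.index("z_surv[0]")
    draws = pop_fit.theta[:, :, i].ravel()
    assert abs(draws.mean()) < 0.35
    assert 0.65 < draws.std() < 1.35


def constructed_samples(N0, counts_years=1, detect_p=0.5, family="poisson", S=3):
    cfg = ModelConfig(
        bin_edges=np.append(np.arange(1.0, float(S + 1)), np.inf), family=family
    )
    T = counts_years
    return cfg, PosteriorSamples.from_paths(
        years=np.arange(2000, 2000 + T),
        config=cfg,
        detect=np.full((S, T), detect_p),
        surv=np.full(T, 0.8),
        recruit=np.zeros(T),
        N0=np.asarray(N0, dtype=float),
        phi=10.0,
    )


class TestPosteriorPredictiveCheck:
    def test_degenerate_tie_gives_half(self):
        # lambda = 0 under Poisson: every replicate equals the observed zero
        cfg, s = constructed_samples(N0=[0.0, 0.0, 0.0])
        data = [kp.SizeFrequency(2000, "A", "1", np.zeros(3, dtype=int))]
        p = posterior_predictive_check(s, data, seed=0)
        assert p["total_count"][0] == pytest.approx(0.5)

    def test_observed_above_all_replicates_gives_zero(self):
        cfg, s = constructed_samples(N0=[0.0, 0.0, 0.0])
        data = [kp.SizeFrequency(2000, "A", "1", np.array([2, 1, 2]))]
        p = posterior_predictive_check(s, data, seed=0)
        assert p["total_count"][0] == 0.0

    def test_calibrated_on_self_simulated_data(self, pop_sim, pop_fit):
        """Data were generated by the model family being fitted, so the
        Bayesian p-values should rarely be extreme."""
        p = posterior_predictive_check(pop_fit, pop_sim.observations, seed=1)
        vals = np.concatenate([p["total_count"], p["mean_size"]])
        vals = vals[~np.isnan(vals)]
        assert np.all((vals >= 0) & (vals <= 1))
        frac = np.mean((vals > 0.05) & (vals < 0.95))
        assert frac >= 0.75


class TestHindcast:
    def test_identical_draws_zero_width(self):
        cfg, s = constructed_samples(N0=[4.0, 2.0, 1.0])
        h = hindcast_density(s)
        assert np.allclose(h["lo90"], h["mean"])
        assert np.allclose(h["hi90"], h["mean"])

    def test_matches_percentile_oracle(self, pop_fit):
        h = hindcast_density(pop_fit)
        total = pop_fit.lam().sum(axis=1)

        def manual_pct(x, q):
            x = np.sort(x)
            r = q / 100 * (len(x) - 1)
            lo = int(np.floor(r))
            hi = min(lo + 1, len(x) - 1)
            return x[lo] + (r - lo) * (x[hi] - x[lo])

        for t in range(0, len(pop_fit.years), 5):
            assert h["lo90"][t] == pytest.approx(manual_pct(total[:, t], 5.0), rel=1e-12)
            assert h["hi90"][t] == pytest.approx(manual_pct(total[:, t], 95.0), rel=1e-12)
        assert np.all(h["lo90"] <= h["hi90"])

    def test_true_detected_density_mostly_inside_band(self, pop_sim, pop_fit):
        truth = (pop_sim.detection * pop_sim.latent.N).sum(axis=0)
        h = hindcast_density(pop_fit)
        inside = np.mean((truth >= h["lo90"]) & (truth <= h["hi90"]))
        assert inside >= 0.8


class TestFoldChange:
    def test_constant_process_gives_exactly_one(self):
        cfg = ModelConfig()
        s = PosteriorSamples.from_paths(
            years=np.arange(2010, 2018),
            config=cfg,
            detect=np.full((10, 8), 0.3),
            surv=np.full(8, 0.9),
            recruit=np.full(8, 5.0),
            N0=np.full(10, 10.0),
            phi=5.0,
        )
        fc = fold_change_summary(s, 2013)
        for proc in ("detection", "recruitment", "survival"):
            assert fc.draws[proc][0] == pytest.approx(1.0, abs=1e-12)

    def test_window_edge_rejected(self, pop_fit):
        with pytest.raises(InvalidParamsError):
            fold_change_summary(pop_fit, 2021)
        with pytest.raises(InvalidParamsError):
            fold_change_summary(pop_fit, 1998)
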