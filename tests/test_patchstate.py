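"""Patch-state discriminant, transition bookkeeping, logistic thresholds."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal

import kelpatch as kp
from kelpatch.errors import DataError, InvalidParamsError
from kelpatch.patchstate import (
    STATES,
    LogisticFit,
    lda_classify,
    lda_train,
    logistic_fit,
    select_model,
    threshold_50,
    transition_table,
)


def gaussian_blobs(seed=0, n=120, d=4, sep=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.array(["forest"] * n + ["barren"] * n)
    return X, y


class TestLDA:
    def test_separable_classes_perfectly_recovered(self):
        X, y = gaussian_blobs(sep=8.0)
        m = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        assert m.misclassified == 0
        assert m.entropy_r2 > 0.95

    def test_random_labels_give_near_zero_entropy_r2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (400, 3))
        y = np.where(rng.random(400) < 0.5, "forest", "barren")
        m = lda_train(X, y, feature_names=("a", "b", "c"))
        assert abs(m.entropy_r2) < 0.05

    def test_class_mean_classifies_to_its_class(self):
        X, y = gaussian_blobs()
        m = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        labels, _ = lda_classify(m, m.class_means)
        assert list(labels) == list(STATES)

    def test_midpoint_posterior_is_half(self):
        X, y = gaussian_blobs(sep=5.0)
        m = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        m.priors = np.array([0.5, 0.5])
        mid = m.class_means.mean(axis=0)
        labels, probs = lda_classify(m, mid[None, :])
        assert probs[0] == pytest.approx([0.5, 0.5], abs=1e-9)
        assert labels[0] == "forest"  # documented tie rule

    def test_posteriors_match_gaussian_density_oracle(self):
        X, y = gaussian_blobs(seed=2, sep=3.0)
        m = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        rng = np.random.default_rng(3)
        Q = rng.normal(2, 3, (20, 4))
        _, probs = lda_classify(m, Q)
        for i in range(20):
            dens = np.array(
                [
                    pi * multivariate_normal.pdf(Q[i], mean=mu, cov=m.pooled_cov)
                    for mu, pi in zip(m.class_means, m.priors)
                ]
            )
            assert probs[i] == pytest.approx(dens / dens.sum(), rel=1e-9)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = gaussian_blobs(seed=4, sep=2.0, n=200)
        m = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        ref = LinearDiscriminantAnalysis().fit(X, y)
        rng = np.random.default_rng(5)
        Q = rng.normal(1, 2, (200, 4))
        ours, _ = lda_classify(m, Q)
        agree = np.mean(ours == ref.predict(Q))
        assert agree > 0.99

    def test_affine_rescaling_of_one_feature_is_invariant(self):
        X, y = gaussian_blobs(seed=6, sep=2.5)
        rng = np.random.default_rng(7)
        Q = rng.normal(1, 2, (50, 4))
        m1 = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        l1, _ = lda_classify(m1, Q)
        Xs, Qs = X.copy(), Q.copy()
        Xs[:, 2] = 13.0 * Xs[:, 2] - 4.0
        Qs[:, 2] = 13.0 * Qs[:, 2] - 4.0
        m2 = lda_train(Xs, y, feature_names=("a", "b", "c", "d"))
        l2, _ = lda_classify(m2, Qs)
        assert np.array_equal(l1, l2)

    def test_singular_covariance_regularised_with_warning(self):
        X, y = gaussian_blobs(seed=8)
        X[:, 3] = X[:, 2]  # collinear feature
        with pytest.warns(UserWarning):
            m = lda_train(X, y, feature_names=("a", "b", "c", "d"))
        labels, _ = lda_classify(m, X)
        assert m.misclassified < 5

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            lda_train(np.zeros((3, 2)), ["forest", "forest", "barren"])


def toy_classified():
    """Five sites, hand-assigned states over two consecutive years."""
    rows = []
    states = {
        "A": ("forest", "forest"),
        "B": ("forest", "barren"),
        "C": ("barren", "forest"),
        "D": ("barren", "barren"),
        "E": ("forest", "forest"),
    }
    for site, (s17, s18) in states.items():
        rows.append(dict(site=site, year=2017, state=s17, exposed_density=1.0, concealed_density=2.0))
        rows.append(dict(site=site, year=2018, state=s18, exposed_density=1.5, concealed_density=2.0))
    # a site with non-consecutive years must not be paired
    rows.append(dict(site="F", year=2017, state="forest", exposed_density=1.0, concealed_density=0.0))
    rows.append(dict(site="F", year=2019, state="barren", exposed_density=9.0, concealed_density=0.0))
    return pd.DataFrame(rows)


class TestTransitionTable:
    def test_hand_enumerated_counts(self):
        t = transition_table(toy_classified())
        assert t.counts == {"persisted": 3, "forward": 1, "reverse": 1}
        assert len(t.records) == 5
        assert sum(t.counts.values()) == len(t.records)

    def test_all_forest_persists(self):
        df = pd.DataFrame(
            [
                dict(site=s, year=y, state="forest", exposed_density=0.5, concealed_density=1.0)
                for s in "ABC"
                for y in (2017, 2018)
            ]
        )
        t = transition_table(df)
        assert t.counts == {"persisted": 3, "forward": 0, "reverse": 0}

    def test_duplicate_site_year_rejected(self):
        df = toy_classified()
        with pytest.raises(DataError):
            transition_table(pd.concat([df, df.iloc[[0]]]))

    def test_outcome_consistent_with_states(self):
        t = transition_table(toy_classified())
        for r in t.records:
            assert r.outcome == int(r.start_state != r.end_state)


def simulated_records(seed=0, n=240, b0=-2.0, b1=1.5):
    """Transitions driven purely by log exposed density."""
    rng = np.random.default_rng(seed)
    log_d = rng.normal(0.5, 1.2, n)
    y = (rng.random(n) < expit(b0 + b1 * log_d)).astype(int)
    return pd.DataFrame(
        {
            "log_exposed": log_d,
            "state": 0.0,
            "outcome": y,
            "start_state": "forest",
            "exposed_density": np.exp(log_d),
            "concealed_density": rng.normal(2, 1, n),
        }
    )


class TestLogisticFit:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        df = simulated_records()
        fit = logistic_fit(df, ("log_exposed", "concealed"))
        X = sm.add_constant(df[["log_exposed", "concealed_density"]].to_numpy())
        ref = sm.GLM(df["outcome"], X, family=sm.families.Binomial()).fit()
        ours = np.array([fit.coef["intercept"], fit.coef["log_exposed"], fit.coef["concealed"]])
        assert np.max(np.abs(ours - ref.params)) < 1e-6
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_balanced_outcome_independent_of_predictor(self):
        # exact symmetry: every x value appears once with y=0 and once with y=1
        x = np.linspace(-2, 2, 20)
        df = pd.DataFrame(
            {
                "log_exposed": np.concatenate([x, x]),
                "outcome": np.r_[np.zeros(20), np.ones(20)],
            }
        )
        fit = logistic_fit(df, ("log_exposed",))
        assert fit.coef["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.coef["log_exposed"] == pytest.approx(0.0, abs=1e-10)

    def test_complete_separation_flagged_not_raised(self):
        df = simulated_records(n=40)
        df["outcome"] = (df["log_exposed"] > 0.5).astype(int)
        with pytest.warns(RuntimeWarning):
            fit = logistic_fit(df, ("log_exposed",))
        assert fit.separation

    def test_noise_predictor_never_lowers_deviance_but_raises_aicc(self):
        lls, daicc = [], []
        for seed in range(10):
            df = simulated_records(seed=seed)
            base = logistic_fit(df, ("log_exposed",))
            noisy = logistic_fit(df, ("log_exposed", "concealed"))
            assert noisy.loglik >= base.loglik - 1e-8
            daicc.append(noisy.aicc - base.aicc)
        assert np.mean(daicc) > 0

    def test_degenerate_outcomes_rejected(self):
        df = simulated_records(n=20)
        df["outcome"] = 1
        with pytest.raises(DataError):
            logistic_fit(df, ("log_exposed",))


class TestSelectModel:
    def test_true_single_predictor_wins_in_18_of_20_replicates(self):
        candidates = [("log_exposed",), ("concealed",), ("state",), ("concealed", "state")]
        wins = 0
        for seed in range(20):
            df = simulated_records(seed=100 + seed)
            df["state"] = np.random.default_rng(seed).integers(0, 2, len(df)).astype(float)
            best, _ = select_model(candidates, df)
            wins += best.terms == ("log_exposed",)
        assert wins >= 18

    def test_duplicate_candidates_first_wins(self):
        df = simulated_records()
        best, table = select_model([("log_exposed",), ("log_exposed",)], df)
        assert table["dAICc"].tolist() == [0.0, 0.0]
        assert best.terms == ("log_exposed",)


def manual_fit(coef, log_offset=0.0, terms=("log_exposed",)):
    return LogisticFit(
        terms=tuple(terms),
        coef=coef,
        loglik=0.0,
        aicc=0.0,
        mcfadden_r2=0.0,
        n=0,
        converged=True,
        separation=False,
        log_offset=log_offset,
    )


class TestThreshold50:
    def test_closed_form_unit_slope(self):
        fit = manual_fit({"intercept": 0.0, "log_exposed": 1.0})
        th = threshold_50(fit, "forest")
        assert th.density == pytest.approx(1.0)

    def test_matches_grid_search_oracle(self):
        df = simulated_records(seed=3)
        fit = logistic_fit(df, ("log_exposed", "concealed"))
        th = threshold_50(fit, "forest", df)
        conc = df["concealed_density"].mean()
        grid = np.linspace(-8, 8, 2_000_001)
        p = expit(
            fit.coef["intercept"]
            + fit.coef["log_exposed"] * grid
            + fit.coef["concealed"] * conc
        )
        cross = grid[np.argmin(np.abs(p - 0.5))]
        assert th.density == pytest.approx(np.exp(cross), rel=1e-4)

    def test_zero_slope_rejected(self):
        fit = manual_fit({"intercept": 1.0, "log_exposed": 0.0})
        with pytest.raises(InvalidParamsError):
            threshold_50(fit, "forest")

    def test_out_of_range_threshold_flagged_extrapolated(self):
        df = simulated_records(seed=4)
        fit = manual_fit({"intercept": -50.0, "log_exposed": 1.0})
        th = threshold_50(fit, "forest", df)
        assert th.extrapolated


def test_hysteresis_recovered_on_synthetic_mosaics():
    """Mosaics generated with distinct forward/reverse thresholds yield a
    recovered forward threshold above the reverse threshold."""
    from conftest import true_state_transitions

    ok = 0
    for seed in (11, 12, 13, 14, 15):
        m = kp.simulate_mosaic(kp.MosaicScenario(seed=seed))
        table = true_state_transitions(m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = logistic_fit(table, ("log_exposed", "state", "log_exposed:state"))
        fwd = threshold_50(fit, "forest", table).density
        rev = threshold_50(fit, "barren", table).density
        ok += fwd > rev
    assert ok >= 4
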