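"""Deterministic parts of the state-space model: projection, expected
counts, count likelihood."""

import numpy as np
import pytest
from scipy.stats import nbinom

import kelpatch as kp
from kelpatch.errors import DataError, DimensionError, InvalidParamsError
from kelpatch.growth import GrowthMatrix
from kelpatch.popmodel import DemographicParams, log_likelihood


def toy_G():
    return GrowthMatrix(np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]]))


class TestProjectPopulation:
    def test_recruitment_only(self):
        out = kp.project_population(np.zeros(3), toy_G(), survival_t=0.9, recruits_t=12.0)
        assert np.array_equal(out, [12.0, 0.0, 0.0])

    def test_extinction(self):
        out = kp.project_population(np.full(3, 5.0), toy_G(), 0.0, 0.0)
        assert np.array_equal(out, np.zeros(3))

    def test_hand_computed_three_class(self):
        # N@G = (5, 10, 15); x0.8 = (4, 8, 12); +2 recruits in class 1
        out = kp.project_population(np.array([10.0, 10.0, 10.0]), toy_G(), 0.8, 2.0)
        assert np.allclose(out, [6.0, 8.0, 12.0], atol=1e-12)

    def test_total_density_conserved_without_mortality(self):
        rng = np.random.default_rng(0)
        G = kp.build_growth_matrix(kp.GrowthParams(7.0, 0.3, 0.4), kp.default_bin_edges())
        N = rng.uniform(0, 50, 10)
        out = kp.project_population(N, G, survival_t=1.0, recruits_t=0.0)
        assert out.sum() == pytest.approx(N.sum(), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(InvalidParamsError):
            kp.project_population(np.array([-1.0, 0, 0]), toy_G(), 0.5, 0.0)
        with pytest.raises(InvalidParamsError):
            kp.project_population(np.zeros(3), toy_G(), 1.5, 0.0)


class TestExpectedCounts:
    def test_limits(self):
        N = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(kp.expected_counts(N, np.zeros((3, 4))), np.zeros((3, 4)))
        assert np.array_equal(kp.expected_counts(N, np.ones((3, 4))), N)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        N = rng.uniform(0, 30, (4, 5))
        det = rng.uniform(0, 1, (4, 5))
        lam = kp.expected_counts(N, det)
        for k in range(4):
            for t in range(5):
                assert lam[k, t] == det[k, t] * N[k, t]

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            kp.expected_counts(np.zeros((3, 4)), np.zeros((4, 3)))


def make_params(T=1, S=3, log_init=None, detect_logit=40.0, phi=5.0):
    return DemographicParams(
        recruit_base=0.0,
        surv_base=0.0,
        detect_base=np.full(S, detect_logit),
        year_fx_recruit=np.zeros(T),
        year_fx_surv=np.zeros(T),
        year_fx_detect=np.zeros(T),
        sd_recruit=0.5,
        sd_surv=0.5,
        sd_detect=0.5,
        overdispersion=phi,
        log_init=np.zeros(S) if log_init is None else np.asarray(log_init, dtype=float),
    )


class TestLogLikelihood:
    def test_vanishing_rate_limit(self):
        # detection -> 0 and counts all zero: P(0) -> 1, log-lik -> 0
        data = [kp.SizeFrequency(2000, "A", "1", np.zeros(3, dtype=int))]
        params = make_params(detect_logit=-200.0)
        G = toy_G()
        assert log_likelihood(params, data, G) == pytest.approx(0.0, abs=1e-8)

    def test_matches_nbinom_pmf_oracle(self):
        # detection ~ 1 in a single year: lambda = exp(log_init)
        y = np.array([3, 0, 7])
        lam = np.exp([1.0, 0.2, 2.0])
        phi = 4.0
        data = [kp.SizeFrequency(2000, "A", "1", y)]
        params = make_params(log_init=[1.0, 0.2, 2.0], phi=phi)
        ll = log_likelihood(params, data, toy_G())
        oracle = nbinom.logpmf(y, phi, phi / (phi + lam)).sum()
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_poisson_family_matches_scipy(self):
        from scipy.stats import poisson

        y = np.array([2, 5, 0])
        lam = np.exp([0.5, 1.5, -1.0])
        data = [kp.SizeFrequency(2000, "A", "1", y)]
        params = make_params(log_init=[0.5, 1.5, -1.0])
        ll = log_likelihood(params, data, toy_G(), family="poisson")
        assert ll == pytest.approx(poisson.logpmf(y, lam).sum(), abs=1e-10)

    def test_additive_over_duplicated_data(self):
        rng = np.random.default_rng(2)
        data = [
            kp.SizeFrequency(2000 + t, "A", str(i), rng.integers(0, 20, 3))
            for t in range(3)
            for i in range(2)
        ]
        params = make_params(T=3, detect_logit=0.0)
        G = toy_G()
        single = log_likelihood(params, data, G)
        double = log_likelihood(params, data + data, G)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(DataError):
            kp.SizeFrequency(2000, "A", "1", np.array([1.5, 2.0, 3.0]))

    def test_non_contiguous_years_rejected(self):
        data = [
            kp.SizeFrequency(2000, "A", "1", np.zeros(3, dtype=int)),
            kp.SizeFrequency(2003, "A", "1", np.zeros(3, dtype=int)),
        ]
        with pytest.raises(DataError):
            log_likelihood(make_params(T=2), data, toy_G())
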