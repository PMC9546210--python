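"""Shared fixtures: one synthetic survey + fit per scenario, reused suite-wide."""

import numpy as np
import pandas as pd
import pytest

import kelpatch as kp

#: sampler settings for study-condition fits (chosen to keep a fit ~20 s)
FIT_KW = dict(chains=2, draws=2000, warmup=3000, thin=2)


@pytest.fixture(scope="session")
def pop_sim():
    """Default study conditions: 23 years, x10 detection step, x2 recruitment."""
    return kp.simulate_population(kp.PopScenario(seed=7))


@pytest.fixture(scope="session")
def pop_fit(pop_sim):
    return kp.fit_mcmc(pop_sim.observations, seed=107, **FIT_KW)


@pytest.fixture(scope="session")
def two_proc_sim():
    """Two varying processes: detection x9 and recruitment x2 at the same year."""
    years = np.arange(1999, 2022)
    sc = kp.PopScenario(
        seed=11,
        detection=kp.step_path(years, 0.05, 0.45, 2014),
        recruitment=kp.step_path(years, 15.0, 30.0, 2014),
    )
    return kp.simulate_population(sc)


@pytest.fixture(scope="session")
def two_proc_fit(two_proc_sim):
    return kp.fit_mcmc(two_proc_sim.observations, seed=111, **FIT_KW)


@pytest.fixture(scope="session")
def mosaic():
    return kp.simulate_mosaic(kp.MosaicScenario(seed=3))


def true_state_transitions(mosaic) -> kp.TransitionTable:
    """Transition table built from the generator's true states."""
    df = pd.DataFrame(
        {
            "site": [s.site_id for s in mosaic.surveys],
            "year": [s.year for s in mosaic.surveys],
            "exposed_density": [s.exposed_density for s in mosaic.surveys],
            "concealed_density": [s.concealed_density for s in mosaic.surveys],
        }
    ).merge(mosaic.states, on=["site", "year"])
    df["state"] = df["true_state"]
    return kp.transition_table(df)


def equilibrium_state(config: kp.ModelConfig, survival: float, recruits: float) -> np.ndarray:
    """Stationary size structure under constant rates (for counterfactual tests)."""
    G = config.growth_matrix().probs
    N = np.zeros(config.n_classes)
    for _ in range(400):
        N = survival * (N @ G)
        N[0] += recruits
    return N
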