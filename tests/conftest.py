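import numpy as np
import pytest

from deerssm import (
    ModelParams,
    SurveyData,
    TimeIndex,
    scenario_from_study_defaults,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def study_scenario():
    return scenario_from_study_defaults()


@pytest.fixture(scope="session")
def small_dataset(study_scenario):
    """One simulated 12-year dataset at the study-default scenario."""
    return simulate_dataset(study_scenario, seed=11)


def make_toy(rng: np.random.Generator, T: int = 8, routes=("A", "B")):
    """Random small survey dataset + in-support parameters for oracle tests."""
    time = TimeIndex(2007, T // 4)
    W, M = time.n_winters, len(routes)
    O = rng.integers(0, 12, size=(T, M))
    data = SurveyData(
        time=time,
        routes=tuple(routes),
        road_counts=np.where(O > 0, rng.integers(0, 30, size=(T, M)), 0),
        road_occasions=O,
        route_area_ratio=rng.uniform(2e-4, 2e-3, size=M),
        block_counts=rng.integers(0, 25, size=W),
        block_area_ratio=rng.uniform(0.02, 0.06, size=W),
        harvest=rng.integers(0, 15, size=T),
        effort=rng.uniform(0, 25, size=T),
        carcasses=rng.integers(0, 30, size=W),
        carcass_area_ratio=rng.uniform(0.05, 0.12, size=W),
        snow_days=rng.uniform(0, 90, size=W),
        snow_max=rng.uniform(30, 145, size=W),
    )
    params = ModelParams(
        NL=rng.normal(6.0, 1.0, size=T),
        rl=rng.normal(0.0, 0.2, size=T),
        hl=rng.normal(-4.0, 1.0, size=T - 1),
        dl=rng.normal(-2.0, 1.0, size=W),
        rsl=rng.normal(0.0, 0.5, size=T),
        hm=rng.normal(-5, 1),
        rho=rng.normal(0.1, 0.05),
        b=rng.normal(-4, 1),
        a=rng.normal(0.05, 0.03),
        sigma=rng.uniform(0.1, 2.0, size=6),
        R=rng.uniform(0.05, 0.9, size=M),
        bc=rng.uniform(0.05, 0.9),
        rD=rng.uniform(0.05, 0.9),
    )
    return data, params
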