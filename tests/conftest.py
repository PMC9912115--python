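"""Shared fixtures: the expensive full-length closed-loop runs are computed
once per session and shared between the acceptance tests."""

from __future__ import annotations

import pytest
from hypothesis import settings

from presscontrol import make_scenario, run_closed_loop
from presscontrol.params import ToolingGeometry, get_parameters

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Seeds for the shared full-length runs; fixed so every session reproduces
# the same streams.
CS1_SEED = 11
CS2_SEED = 12


@pytest.fixture(scope="session")
def geometry():
    return ToolingGeometry()


@pytest.fixture(scope="session")
def nominal_params():
    return get_parameters("no_pmm")


@pytest.fixture(scope="session")
def cs2_params():
    return get_parameters("cs2_nominal")


@pytest.fixture(scope="session")
def run_cs1_no_pmm():
    sc = make_scenario("cs1_no_pmm", seed=CS1_SEED)
    return run_closed_loop(sc, mode="mhe_nmpc")


@pytest.fixture(scope="session")
def run_cs1_mild_pmm():
    sc = make_scenario("cs1_mild_pmm", seed=CS1_SEED)
    return run_closed_loop(sc, mode="mhe_nmpc")


@pytest.fixture(scope="session")
def run_cs1_high_pmm():
    sc = make_scenario("cs1_high_pmm", seed=CS1_SEED)
    return run_closed_loop(sc, mode="mhe_nmpc")


@pytest.fixture(scope="session")
def run_cs2_mhe():
    sc = make_scenario("cs2_silica_steps", seed=CS2_SEED)
    return run_closed_loop(sc, mode="mhe_nmpc")


@pytest.fixture(scope="session")
def run_cs2_nmpc_only():
    # first disturbance cycle is enough for the estimator-vs-fixed-model
    # comparison; keeps the session budget down
    sc = make_scenario("cs2_silica_steps", seed=CS2_SEED, horizon_end=1000)
    return run_closed_loop(sc, mode="nmpc_only")
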