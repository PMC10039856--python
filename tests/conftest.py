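"""Shared fixtures: seeded synthetic datasets reused across test modules."""

import warnings

import numpy as np
import pytest

import pathmodes as pm


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Synthetic pathways legitimately trigger small-list / no-mode warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def two_module_sim():
    """Canonical planted two-module dataset (600 cells, 200-gene pathway)."""
    return pm.simulate_counts(pm.two_module_pathway_spec(seed=0))


@pytest.fixture(scope="session")
def two_module_lognorm(two_module_sim):
    return pm.lognormalize(two_module_sim.expression)


@pytest.fixture(scope="session")
def two_module_result(two_module_sim, two_module_lognorm):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pm.detect_pathway_modes(
            two_module_lognorm, two_module_sim.pathways["pathway_AB"]
        )


@pytest.fixture(scope="session")
def annotation_sim():
    """Three balanced populations with disjoint marker modules."""
    return pm.simulate_counts(pm.annotation_spec(seed=0))


@pytest.fixture(scope="session")
def annotation_lognorm(annotation_sim):
    return pm.lognormalize(annotation_sim.expression)


@pytest.fixture(scope="session")
def marker_activity(annotation_sim, annotation_lognorm):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pm.first_mode_activity(annotation_lognorm, annotation_sim.markers)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
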