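"""Shared fixtures: small network configs and the compartmental model.

Session-scoped fixtures cache expensive artifacts (segmentized graphs,
calibrated parameters) so the suite stays within a desk-scale runtime.
"""

from __future__ import annotations

import pytest

from coopnet.compartmental import (
    calibrate_rm,
    make_synthetic_morphology,
    segmentize,
)
from coopnet.network_sim import NetworkConfig


@pytest.fixture(scope="session")
def morphology():
    return make_synthetic_morphology(seed=0)


@pytest.fixture(scope="session")
def calibrated_graph(morphology):
    """Compartment graph with Rm calibrated to the 78 MOhm target."""
    params = calibrate_rm(segmentize(morphology), 78.0)
    return segmentize(morphology, params)


@pytest.fixture()
def small_config():
    """Cheap single-network config for contract tests (not the gamma regime)."""
    return NetworkConfig(n_pyr=50, duration=500.0, seed=7)


@pytest.fixture()
def default_config():
    """The calibrated operating point, shortened to 2 s."""
    return NetworkConfig(duration=2000.0, seed=0)

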