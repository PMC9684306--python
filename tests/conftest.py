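"""Shared fixtures: replication studies are expensive, so the benchmark
runs used by several tests execute once per session."""

import numpy as np
import pytest
from hypothesis import settings

from bmrfnet import (
    PRESETS,
    BMRF,
    MCMCConfig,
    elicit_priors,
    m3_fixture,
    run_replication_study,
    sample_mvn,
    standardize,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def m11_study():
    """M1.1 (p=25, S=0.05, n=250) replication study, both prior setups, R=20."""
    return run_replication_study(
        PRESETS["M1.1"], R=20, base_seed=0, methods=("BMRF.O", "BMRF.P")
    )


@pytest.fixture(scope="session")
def m3_study():
    """Fixed two-hub network study (p=50, n=250), R=10, hub degrees recorded."""
    return run_replication_study(
        PRESETS["M3"],
        R=10,
        base_seed=0,
        methods=("BMRF.O", "BMRF.P"),
        hub_nodes=(1, 3),
    )


@pytest.fixture(scope="session")
def m21_study():
    """Small scale-free (M2.1, p=25) study for probability calibration checks."""
    return run_replication_study(
        PRESETS["M2.1"], R=3, base_seed=0, methods=("BMRF.O",)
    )


@pytest.fixture(scope="session")
def m3_single_fit():
    """One objective-prior fit on fixed-network data, for recovery checks."""
    truth, omega = m3_fixture()
    x = standardize(sample_mvn(omega, 250, seed=42))
    priors = elicit_priors(x, "BMRF.O", top_fraction=0.10)
    model = BMRF(x, priors=priors)
    res = model.fit(seed=7)
    return truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(20221110)
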