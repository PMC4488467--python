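import dataclasses

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from vespawing.config import (
    ColonySpec,
    ErrorStudyDesign,
    default_config,
)
from vespawing import pipeline, wing_synth

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so outcomes
    # cannot depend on which other tests ran first
    return np.random.default_rng(20150701)


@pytest.fixture(scope="session")
def study():
    """One full default-condition simulated study, reused across tests."""
    return wing_synth.simulate_study(default_config(), seed=42)


@pytest.fixture(scope="session")
def tiny_config():
    """Scaled-down study conditions for fast pipeline round trips."""
    cfg = default_config()
    return dataclasses.replace(
        cfg,
        colonies=(
            ColonySpec(30, (0.4, 0.3, 0.2, 0.1)),
            ColonySpec(28, (0.4, 0.3, 0.2, 0.1)),
        ),
        error_study=ErrorStudyDesign(8, 2, 2),
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny_run")
    report, manifest = pipeline.run_pipeline(
        tiny_config, outdir, seed=7, angle_draws=200
    )
    return outdir, report, manifest
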