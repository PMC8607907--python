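import numpy as np
import pytest

from headingflow import (
    ExperimentSpec,
    MSTdParams,
    MTParams,
    SceneConfig,
    generate_sequence,
    run_experiment,
    summarize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_flow():
    """A standard no-noise stimulus at a -20 deg heading."""
    return generate_sequence(SceneConfig(heading_deg=-20.0), 7)


@pytest.fixture(scope="session")
def short_flow():
    """A short stimulus for cheap model-level tests."""
    return generate_sequence(SceneConfig(heading_deg=10.0, n_frames=10), 11)


@pytest.fixture(scope="session")
def peripheral_sweep():
    """Full 21-heading sweep of the peripheral (gamma = 0.5) model.

    Reduced to 10 model samplings per heading; shared across tests that
    examine the bias/variability structure of the default model.
    """
    spec = ExperimentSpec(name="mstd_heading", values=(0.5,), runs=10, base_seed=0)
    results = run_experiment(spec)
    return results, summarize(results)
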