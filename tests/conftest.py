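import numpy as np
import pytest

from tailvirkit.config import PipelineConfig
from tailvirkit.pipeline import run_all
from tailvirkit.synthetic import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle_and_truth():
    """One default synthetic bundle shared by read-only tests."""
    return simulate_bundle(SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def pipeline_result(bundle_and_truth):
    bundle, _ = bundle_and_truth
    return run_all(bundle, PipelineConfig(rng_seed=11), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
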