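import numpy as np
import pytest

from heatmir.config import PipelineConfig
from heatmir.synthetic import make_fixture


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """One tiny synthetic study bundle shared across the session."""
    outdir = tmp_path_factory.mktemp("fixture") / "tiny"
    config, truth = make_fixture("tiny", seed=11, outdir=outdir)
    return config, truth, outdir


@pytest.fixture(scope="session")
def tiny_run(tiny_fixture, tmp_path_factory):
    """The tiny bundle processed end to end."""
    from heatmir.pipeline import run_pipeline

    config, truth, _ = tiny_fixture
    rundir = tmp_path_factory.mktemp("run") / "tiny"
    result = run_pipeline(config, rundir)
    return result, truth, rundir


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
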