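import numpy as np
import pytest

from ecazones.dataio import PointSurvey, RasterGrid
from ecazones.pipeline import PipelineConfig, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_template():
    """5×5 grid of 20 m cells covering (0,100)²."""
    return RasterGrid.empty(0.0, 0.0, 20.0, 5, 5)


@pytest.fixture
def random_survey(rng):
    return PointSurvey(rng.uniform(0, 100, 20), rng.uniform(0, 100, 20),
                       rng.normal(50.0, 10.0, 20), variable_name="eca")


@pytest.fixture(scope="session")
def default_scenario_42():
    from ecazones.synthetic import default_scenario
    return default_scenario(seed=42)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The default pipeline run twice with the same seed, for
    determinism and composition checks."""
    dirs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"run_{tag}") / "run"
        cfg = PipelineConfig.from_dict({"seed": 42, "outdir": str(out)})
        dirs.append(run_pipeline(cfg))
    return dirs
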