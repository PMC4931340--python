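import numpy as np
import pytest

from dictycomp.pipeline import RunConfig, load_bundle, run_pipeline
from dictycomp.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160630)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """20 mixed families (duplication/loss/LGT/divergence) on disk."""
    path = tmp_path_factory.mktemp("data") / "small"
    cfg = SimulationConfig(n_families=20, seed=11, lgt_prob=0.2)
    generate_dataset(cfg, path)
    return path


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("run") / "small"
    cfg = RunConfig(data_dir=small_dataset, out_dir=out, seed=11)
    result = run_pipeline(cfg)
    result["out_dir"] = out
    result["bundle"] = load_bundle(small_dataset)
    return result
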