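import numpy as np
import pytest

from rootecon import SimulationConfig, make_fixture, run_pipeline
from rootecon.pipeline import PipelineConfig
from rootecon.synthetic_data import simulate_genotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def small_genotypes():
    """60 genotypes x 120 markers on 3 chromosomes with a little missingness."""
    cfg = SimulationConfig(
        n_genotypes=60, n_blocks=4, n_markers=120, n_chromosomes=3,
        missing_rate=0.05, seed=11,
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A complete tiny synthetic study plus one full pipeline run."""
    root = tmp_path_factory.mktemp("tiny_study")
    fix_dir = make_fixture("tiny", seed=7, out_dir=root / "fixture")
    cfg = PipelineConfig.from_yaml(fix_dir / "config.yaml")
    summary = run_pipeline(cfg, root / "run")
    return dict(fixture=fix_dir, run=root / "run", config=cfg, summary=summary)
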