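import numpy as np
import pytest

from graftomics.config import SimConfig
from graftomics.pipeline import run_all
from graftomics.config import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast, fully featured simulation world for unit tests."""
    return SimConfig(
        n_genes=60,
        gene_length_bp=300,
        intergenic_bp=120,
        depth_mean=20,
        dmp_rate=0.01,
        error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One completed small pipeline run shared by io/pipeline tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        outdir=str(outdir),
        sim=SimConfig(n_genes=60, gene_length_bp=300, intergenic_bp=120,
                      dmp_rate=0.01, error_rate=0.01, seed=5),
    )
    manifest = run_all(cfg)
    return cfg, outdir, manifest
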