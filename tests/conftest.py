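import numpy as np
import pytest

from allomap.pipeline import PipelineConfig, run_pipeline
from allomap.simulate import SimConfig, simulate_truth_set


@pytest.fixture(scope="session")
def truth_small():
    """A compact synthetic study used by oracle comparisons.

    8 ancestral blocks x 6 genes at the default divergence structure;
    no external alignment tools needed to build it.
    """
    return simulate_truth_set(SimConfig(n_blocks=8, genes_per_block=6, seed=123))


@pytest.fixture(scope="session")
def pipeline_small(tmp_path_factory):
    """One full end-to-end run on a small synthetic study (shared)."""
    workdir = tmp_path_factory.mktemp("pipeline_small")
    cfg = PipelineConfig(
        workdir=str(workdir), seed=5,
        sim=SimConfig(n_blocks=6, genes_per_block=5, seed=5, n_dh=100))
    report = run_pipeline(cfg)
    return {"config": cfg, "report": report, "workdir": workdir}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
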