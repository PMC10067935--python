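import numpy as np
import pandas as pd
import pytest

from snp2path import synth
from snp2path.pipeline import PipelineConfig


@pytest.fixture
def small_synth_config():
    """A scaled-down world for fast unit tests (structure, not power)."""
    cfg = synth.SynthConfig(seed=11)
    cfg.n_snps_per_ancestry = {"EA": 60, "AsA": 50}
    cfg.shared_snp_count = 5
    cfg.n_genes_universe = 400
    cfg.ppi_spec = synth.PpiSpec(n_modules=2, module_size=8, p_within=0.9, p_background=0.02, n_background_genes=120)
    cfg.expr_spec = synth.ExprSpec(n_genes=80, n_case=6, n_control=6, set_size=10, n_decoy_sets=2)
    return cfg


@pytest.fixture
def small_pipeline_config(small_synth_config):
    cfg = PipelineConfig()
    cfg.synth = small_synth_config
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_expr(rng, p=30, n=8, prefix="G"):
    genes = [f"{prefix}{i:04d}" for i in range(1, p + 1)]
    samples = [f"S{j:02d}" for j in range(1, n + 1)]
    X = rng.normal(7.0, 1.0, size=(p, n))
    return pd.DataFrame(X, index=genes, columns=samples)
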