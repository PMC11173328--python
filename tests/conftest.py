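import numpy as np
import pytest

from naristat import SimConfig, assign_or, generate_sc_dataset, run_preprocess


@pytest.fixture(scope="session")
def default_sc():
    """Seed-1 naris-occlusion dataset at generator defaults.

    60 ORs (10 resistant), 40 cells per OR per naris, occlusion effect
    exp(-1) on activity genes and exp(+1) on the sensor gene.
    """
    config = SimConfig(seed=1)
    cm, meta, truth = generate_sc_dataset(config)
    return config, cm, meta, truth


@pytest.fixture(scope="session")
def default_prep(default_sc):
    _config, cm, _meta, _truth = default_sc
    return run_preprocess(cm)


@pytest.fixture(scope="session")
def default_assignments(default_sc):
    _config, cm, _meta, _truth = default_sc
    or_genes = [g for g in cm.gene_ids if str(g).startswith("OrS")]
    return assign_or(cm, or_genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
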