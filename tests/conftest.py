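import numpy as np
import pytest

from fliopipe.etdrs import build_feature_table
from fliopipe.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-design synthetic cohort (26/14/14 subjects), FLIO only."""
    cfg = SyntheticConfig(seed=11, octa_slabs=())
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def default_table(default_cohort):
    _, cohort, _ = default_cohort
    return build_feature_table(cohort)


@pytest.fixture(scope="session")
def null_table():
    """Feature table from a cohort with all group effects switched off."""
    cfg = SyntheticConfig(seed=5, octa_slabs=(), effect_ir_ssc_ps=0.0, effect_or_lsc_ps=0.0)
    cohort, _ = generate_cohort(cfg)
    return build_feature_table(cohort)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
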