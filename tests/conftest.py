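import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("pavcall").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def deletion_population():
    """A two-pool DH population with planted pool-specific deletions and dropout."""
    from pavcall.synth import DeletionEvent, PopulationConfig, generate_population

    dels = [
        DeletionEvent(f"chr{c + 1}", s, s + 3, 0.45, 0.05, effect=1.0)
        for c in range(4)
        for s in (20, 70)
    ]
    cfg = PopulationConfig(
        n_per_pool=150,
        n_chrom=4,
        markers_per_chrom=100,
        fst=0.2,
        rho=0.9,
        deletions=dels,
        epsilon=0.02,
        h2=0.6,
        n_trait_qtl=40,
        seed=7,
    )
    cm, truth, pheno = generate_population(cfg)
    return cfg, cm, truth, pheno


@pytest.fixture(scope="session")
def preprocessed(deletion_population):
    from pavcall.preprocess import preprocess

    _, cm, truth, pheno = deletion_population
    dm, fm, report = preprocess(cm, seed=11)
    return dm, fm, report
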