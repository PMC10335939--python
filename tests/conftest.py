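import dataclasses

import numpy as np
import pytest

from ragprint.simulate import (
    GeneratorConfig,
    gen_response_series,
    gen_sc_matrix,
    simulate_sv_cohort,
)


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Reduced cohort for fast unit/property tests."""
    return GeneratorConfig(
        seed=11, ref_length=1_200_000, n_rag_svs=120, n_nonrag_svs=40,
        n_translocation_svs=40,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_sv_cohort(small_cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the generator's default (study-condition) sizes."""
    return simulate_sv_cohort(GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def sc_bundle():
    cfg = GeneratorConfig(seed=7)
    matrix, truth, gene_sets, cluster_labels = gen_sc_matrix(cfg)
    return dict(matrix=matrix, truth=truth, gene_sets=gene_sets,
                cluster_labels=cluster_labels, cfg=cfg)


@pytest.fixture(scope="session")
def response_bundle():
    cfg = GeneratorConfig(seed=13)
    series, truth = gen_response_series(cfg)
    return dict(series=series, truth=truth, cfg=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
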