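from pathlib import Path

import pytest

from sub1_tfscan import (
    GeneEffect,
    SyntheticConfig,
    build_delta_ct_matrix,
    filter_reactions,
    load_catalog,
    simulate_experiment,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated experiment with one planted submergence effect."""
    cfg = SyntheticConfig(
        n_genes=60,
        seed=42,
        frac_low_expressors=0.0,
        effect_table={"TF0001": GeneEffect(sub_ir64=2.0)},
    )
    reactions, truth = simulate_experiment(cfg)
    return cfg, reactions, truth


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    _, reactions, _ = small_dataset
    kept, _ = filter_reactions(reactions)
    return build_delta_ct_matrix(kept)


@pytest.fixture()
def qc_fixture_path():
    return DATA_DIR / "qc_fixture.tsv"
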