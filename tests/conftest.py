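import numpy as np
import pytest

from trio_polygen.synthetic_cohort import (
    AscertainmentSpec,
    SimulationConfig,
    TraitSpec,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def small_config(**overrides) -> SimulationConfig:
    """Compact two-trait study: one ascertained (SCZ) and one null (BMI)."""
    defaults = dict(
        n_trios=100,
        n_variants=200,
        n_blocks=20,
        seed=11,
        subgroup_counts={"AS": 30, "Non_AS": 70},
        trait_specs=(
            TraitSpec("SCZ", 0.2, 0.5, 100_000),
            TraitSpec("BMI", 0.2, 0.5, 100_000),
        ),
        ascertainment=(AscertainmentSpec("AS", "SCZ", 0.9),),
        n_genes_per_tissue=30,
        eqtls_per_gene=3,
    )
    if "n_trios" in overrides and "subgroup_counts" not in overrides:
        defaults["subgroup_counts"] = None
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture
def null_config():
    """No ascertainment anywhere: transmission is exactly Mendelian."""
    return small_config(ascertainment=(), seed=17)
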