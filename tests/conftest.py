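import pytest

import mitocode as mc


@pytest.fixture(scope="session")
def scenario_dataset():
    """One canonical simulated dataset shared by read-only tests."""
    return mc.simulate_dataset(mc.default_scenario(seed=11))


@pytest.fixture(scope="session")
def scenario_result(scenario_dataset):
    ds = scenario_dataset
    return mc.two_stage_analysis(
        ds.reference_sets,
        ds.ortholog_sets,
        {t: mc.standard_table() for t in ds.focal_taxa},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A light all-around dataset for plumbing-level tests."""
    cfg = mc.default_scenario(
        seed=5, n_reference=8, n_genes=5, codons_per_gene=120
    )
    return mc.simulate_dataset(cfg)
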