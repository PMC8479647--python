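import pytest

from ursaburden import SimConfig, default_class_rules, generate_cohort


@pytest.fixture(scope="session")
def rules():
    return default_class_rules()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_cases={"GGE": 300, "NAFE": 200},
        n_controls=300,
        n_genes=300,
        genes_per_set={"setA": 60, "setB": 60, "ctrlset": 60},
        control_sets=("ctrlset",),
        chrx_gene_frac=0.10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A modest two-phenotype cohort reused by read-only tests."""
    return generate_cohort(small_config)
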