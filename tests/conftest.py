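import pytest

from penbayes import synthetic_data as syn
from penbayes.variant_data import (CovariateSet, HeterozygoteCounts,
                                   VariantRecord, VariantTable)


def make_record(pos, ref, alt, affected, unaffected, weight=None, af=None,
                **cov):
    return VariantRecord(pos, ref, alt,
                         HeterozygoteCounts(affected, unaffected),
                         weight=weight, allele_frequency=af,
                         covariates=CovariateSet(**cov))


@pytest.fixture
def small_table():
    """Three variants with distinct counts and covariates."""
    return VariantTable([
        make_record(420, "R", "W", 14, 10, revel=0.9, clinvar_code="P/LP"),
        make_record(186, "V", "M", 1, 22, revel=0.5, clinvar_code="VUS"),
        make_record(50, "A", "T", 0, 40, revel=0.1, clinvar_code="B/LB"),
    ]).finalize()


@pytest.fixture(scope="session")
def synthetic_default():
    """Default-condition synthetic dataset (shared across tests)."""
    return syn.generate(syn.SimulationConfig(
        n_variants=400, protein_length=150, seed=11,
        covariate_effects={"revel": 2.0, "alphamissense": 0.0}))


@pytest.fixture(scope="session")
def toy_structure():
    return syn.generate_toy_structure(50, seed=3)
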