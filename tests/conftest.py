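import pytest

from urometh.models import fit_blcas, fit_ucas
from urometh.signature import HaplotypeSignature
from urometh.simulate import SimulationConfig, make_reference_profiles, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast assay configuration used across module tests."""
    return SimulationConfig(seed=7, coverage=400)


@pytest.fixture(scope="session")
def profiles(small_config):
    return make_reference_profiles(small_config)


@pytest.fixture(scope="session")
def cohort(small_config):
    """Labelled training cohort: 16 HG + 16 LG tissues, 12 urines."""
    return simulate_cohort(small_config, 16, 16, 12)


@pytest.fixture(scope="session")
def fitted_signature(cohort):
    return HaplotypeSignature().fit(cohort.haplotype_table, cohort.truth["class"])


@pytest.fixture(scope="session")
def cohort_features(fitted_signature, cohort):
    return fitted_signature.transform(cohort.haplotype_table)


@pytest.fixture(scope="session")
def fitted_models(cohort, cohort_features):
    feats = cohort_features
    truth = cohort.truth.reindex(feats.index)
    ucas = fit_ucas(feats, (truth["class"] != "URINE").astype(int))
    tissue = feats.loc[truth["class"] != "URINE"]
    blcas = fit_blcas(tissue, (truth.loc[tissue.index, "class"] == "HG").astype(int))
    return ucas, blcas
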