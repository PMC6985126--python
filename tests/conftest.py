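import pytest

from miproteo import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced cohort for fast unit tests (all special genes included)."""
    cfg = CohortConfig(n_genes=400, n_phosphosites=250, n_psm_features=120, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study design (used for cohort-level properties)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def pre_pcr_cores(small_bundle):
    m = small_bundle.manifest
    return m[(m.timepoint == "pre") & (m.group == "pCR")]["core_id"].tolist()


@pytest.fixture()
def pre_nonpcr_cores(small_bundle):
    m = small_bundle.manifest
    return m[(m.timepoint == "pre") & (m.group == "non-pCR")]["core_id"].tolist()
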