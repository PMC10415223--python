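import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cefepime_pbpk.distribution import (
    cefepime_defaults,
    compute_kp_set,
    fu_adjusted,
    load_tissue_compositions,
)
from cefepime_pbpk.engine import (
    DoseRegimen,
    assemble_model,
    default_output_times,
    simulate,
)
from cefepime_pbpk.physiology import build_reference_adult

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def drug():
    return cefepime_defaults()


@pytest.fixture(scope="session")
def compositions():
    return load_tissue_compositions()


@pytest.fixture(scope="session")
def reference_adult():
    return build_reference_adult(70.0, 180.0, 30.0, "male")


@pytest.fixture(scope="session")
def adult_kps(drug, compositions, reference_adult):
    fu = fu_adjusted(drug, reference_adult)
    return compute_kp_set(drug, compositions, fu, phys=reference_adult)


@pytest.fixture(scope="session")
def adult_model(reference_adult, drug, adult_kps):
    return assemble_model(reference_adult, drug, adult_kps)


@pytest.fixture(scope="session")
def healthy_2000mg_result(adult_model):
    """2000 mg / 30 min infusion in the reference adult, with full state."""
    regimen = DoseRegimen(dose_mg=2000, infusion_duration_min=30)
    return simulate(adult_model, regimen, default_output_times(12.0), full_output=True)


@pytest.fixture(scope="session")
def healthy_2000mg_profile(healthy_2000mg_result):
    return healthy_2000mg_result.profile


@pytest.fixture()
def rng():
    return np.random.default_rng(20230619)
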