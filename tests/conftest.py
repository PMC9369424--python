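import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loewe import AdditiveSurface, HillParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Published single-drug fit summaries (mean, SE) for the two allodynia
# assays; dof=33 reflects the study design (6+ dose groups x 6 animals,
# 3 fitted parameters).
def _params(emax, ed50, hill, se_emax, se_ed50, se_hill, label):
    return HillParams(
        emax=emax, ed50=ed50, hill=hill,
        se_emax=se_emax, se_ed50=se_ed50, se_hill=se_hill,
        n_animals=36, dof=33, label=label,
    )


@pytest.fixture(scope="session")
def thc_mech():
    return _params(85.0, 14.0, 2.6, 2.0, 0.8, 0.3, "THC/mechanical_pwt")


@pytest.fixture(scope="session")
def cbd_mech():
    return _params(79.0, 20.0, 1.5, 2.0, 0.6, 0.1, "CBD/mechanical_pwt")


@pytest.fixture(scope="session")
def thc_acetone():
    return _params(52.0, 21.0, 1.7, 3.0, 3.6, 0.4, "THC/acetone")


@pytest.fixture(scope="session")
def cbd_acetone():
    return _params(27.0, 11.0, 2.2, 1.0, 1.0, 0.4, "CBD/acetone")


@pytest.fixture(scope="session")
def mech_surface(cbd_mech, thc_mech):
    return AdditiveSurface(params_a=cbd_mech, params_b=thc_mech)


@pytest.fixture(scope="session")
def acetone_surface(cbd_acetone, thc_acetone):
    return AdditiveSurface(params_a=cbd_acetone, params_b=thc_acetone)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
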