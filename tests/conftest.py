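import pytest
from hypothesis import HealthCheck, settings

import photoinact as pi

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def train():
    return pi.FlashletTrain()


@pytest.fixture(scope="session")
def induction_truth():
    return pi.InductionFit(f0=0.2, fm=1.0, sigma_psii=170.0, rho=0.3)


@pytest.fixture(scope="session", params=["fig3-blue", "fig3-red"],
                ids=["blue", "red"])
def noiseless_preset(request):
    return pi.PRESETS[request.param].noiseless()


@pytest.fixture(scope="session")
def noiseless_blue_tc():
    return pi.make_timecourse(pi.FIG3_BLUE.noiseless())
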