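import pytest

import evcea

#: published log-logistic (scale, shape) fits driving the base case
PUBLISHED_FITS = {
    ("ev_pemb", "pfs"): (0.07657114, 1.267575),
    ("ev_pemb", "os"): (0.02895679, 1.226923),
    ("chemotherapy", "pfs"): (0.1565434, 1.997612),
    ("chemotherapy", "os"): (0.06252743, 1.524174),
}


@pytest.fixture()
def cfg() -> "evcea.RunConfig":
    """A fresh copy of the shipped calibrated base-case configuration."""
    return evcea.default_config()


@pytest.fixture(scope="session")
def base_comparison():
    """The base-case comparison, computed once per session."""
    return evcea.run_model(evcea.default_config())


def dist(arm: str, endpoint: str) -> "evcea.ParametricSurvival":
    return evcea.ParametricSurvival.log_logistic(*PUBLISHED_FITS[(arm, endpoint)])
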