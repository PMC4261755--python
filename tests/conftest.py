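import logging

import pytest
from hypothesis import HealthCheck, settings

from cmapkit.bngl_io import parse_bngl
from cmapkit.contact_map import build_contact_map
from cmapkit.examples import example_family, example_model

settings.register_profile(
    "cmapkit",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cmapkit")

# wildcard-bond notices etc. are expected all over the fixtures
logging.getLogger("cmapkit").setLevel(logging.ERROR)


def cmap_from(text: str, name: str = "m"):
    return build_contact_map(parse_bngl(text, name))


@pytest.fixture(scope="session")
def egfr_model():
    return example_model("synthetic_egfr")


@pytest.fixture(scope="session")
def egfr_cmap(egfr_model):
    return build_contact_map(egfr_model)


@pytest.fixture(scope="session")
def fceri_cmaps():
    return [build_contact_map(m) for m in example_family("synthetic_fceri")]


@pytest.fixture(scope="session")
def fceri_by_name(fceri_cmaps):
    return {c.name: c for c in fceri_cmaps}
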