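import numpy as np
import pytest

from pbtkmix.physiology import BodyPhysiology, Compartment, reference_adult


@pytest.fixture(scope="session")
def adult():
    return reference_adult()


@pytest.fixture()
def two_comp_body():
    """Minimal consistent body: blood plus one perfused tissue."""
    return BodyPhysiology(
        compartments=(
            Compartment(name="blood", volume=5.0, tags=frozenset({"blood"})),
            Compartment(name="rest", volume=65.0, blood_flow=312.0),
        ),
        cardiac_output=312.0,
        body_mass=70.0,
    )


@pytest.fixture(scope="session")
def mixture_run():
    """One shared run of the metals + organics case study (base + one
    positive interaction variant); reused across tests to stay fast."""
    from pbtkmix.interactions import run_mixture_scenario

    return run_mixture_scenario({"variants": {"base": 0.0, "nominal": 1.0}})


def relerr(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    scale = max(np.abs(b).max(), 1e-300)
    return np.abs(a - b).max() / scale
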