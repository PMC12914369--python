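import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uactrials.acss_model import AcssResponse
from uactrials.microbiology import Isolate, UrineResult

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_response(
    typical,
    part="A",
    differential=(0, 0, 0, 0),
    qol=(0, 0, 0),
    dynamics=None,
    patient_id="p1",
    visit_day=0,
):
    return AcssResponse(
        patient_id=patient_id,
        part=part,
        visit_day=visit_day,
        typical=tuple(typical),
        differential=tuple(differential),
        qol=tuple(qol),
        dynamics=dynamics,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def baseline_urine():
    return UrineResult(
        patient_id="p1",
        visit_day=0,
        wbc=50.0,
        isolates=(Isolate(species="Escherichia coli", cfu=1e5),),
    )
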