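import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def poiseuille_result():
    """Steady developing-channel run on the 64x32 validation grid."""
    from ijvflow.runner import poiseuille_case, run_case
    case = poiseuille_case()
    return case, run_case(case, with_valve=False)


@pytest.fixture(scope="session")
def desk_results():
    """The four standard stenosis cases A-D on the reduced (desk) preset,
    run to 3 s with the seeded inlet perturbation; shared across tests."""
    from ijvflow.runner import desk_cases, run_case
    return {c.label: run_case(c) for c in desk_cases(seed=1)}
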