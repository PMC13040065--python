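import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_ball(radius_voxels: int, spacing: float = 0.6, margin: int = 4):
    """Digital ball mask and its radial coordinate grid (mm)."""
    n = 2 * radius_voxels + 2 * margin + 1
    c = (n - 1) / 2.0
    x = (np.arange(n) - c) * spacing
    rr = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2)
    return rr <= radius_voxels * spacing, rr


@pytest.fixture(scope="session")
def phantom22():
    """Default nested-sphere phantom at 22 weeks' gestation."""
    from fetalmorph.synthetic import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(ga_weeks=22.0))


@pytest.fixture(scope="session")
def idp_record22(phantom22):
    from fetalmorph.idps import extract_all_idps

    return extract_all_idps(phantom22, {"fetus_id": "F0", "ga_weeks": 22.0})
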