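import numpy as np
import pytest

from chearray import synth


@pytest.fixture(scope="session")
def toy_model():
    return synth.make_toy_dimer()


@pytest.fixture(scope="session")
def p4_template(toy_model):
    return toy_model.p4_template()


@pytest.fixture(scope="session")
def p4_target(p4_template):
    """A clean 12-A map of the toy P4 domain (the standard docking target)."""
    from chearray import maps

    return maps.simulate_map(
        p4_template.coords, resolution=12.0, voxel_size=2.0, padding=20.0
    )


@pytest.fixture(scope="session")
def spherical_cloud():
    """A roughly isotropic bead cloud for direction-neutral map fixtures."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(250, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts * (15.0 * rng.random((250, 1)) ** (1.0 / 3.0))
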