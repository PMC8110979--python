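import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from airwaymorph.geometry import RigidTransform
from airwaymorph.simulate import GrowthConfig, generate_cohort, template_skull


def random_rigid(rng: np.random.Generator) -> RigidTransform:
    """A uniformly random rotation plus a bounded translation."""
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-80.0, 80.0, 3)
    return RigidTransform(R, t)


@pytest.fixture(scope="session")
def template():
    """Noise-free canonical control template at the reference age."""
    return template_skull()


@pytest.fixture(scope="session")
def default_config():
    return GrowthConfig()


@pytest.fixture(scope="session")
def cohort42():
    """One default-size synthetic study (42 subjects per group)."""
    return generate_cohort(GrowthConfig(), n_per_group=42, seed=11)
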