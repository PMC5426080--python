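import numpy as np
import pytest

from plpgeom import make_aldimine_model
from plpgeom.structure_io import StructureModel


def apply_rigid(model: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Return a deep-ish copy of the model under a global rigid motion."""
    import copy

    out = copy.deepcopy(model)
    for _, _, atom in out.iter_atoms():
        atom.coords = rotation @ atom.coords + translation
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def nat_model():
    return make_aldimine_model(60.0, state="NAT")


@pytest.fixture
def gd_model():
    return make_aldimine_model(66.0, -51.0, state="GD", persulfide=True)


@pytest.fixture
def iaa_model():
    return make_aldimine_model(53.3, -51.4, state="IAA", persulfide=True)


@pytest.fixture
def psf_model():
    return make_aldimine_model(45.0, state="PSF", persulfide=True)
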