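import numpy as np
import pytest

from lofisim.phantom import LesionSpec, PhantomSpec, generate_phantom
from lofisim.volume import Volume


@pytest.fixture(scope="session")
def lesion_phantom():
    """One phantom with a 4 cm^2 three-sub-label lesion on slices 8-12."""
    spec = PhantomSpec(
        lesions=[
            LesionSpec(center=(30.0, 60.0, 10.0), area_cm2=4.0, z_extent_slices=5,
                       contrast=1.8, n_sublabels=3)
        ],
        seed=11,
    )
    vol, labels, mask = generate_phantom(spec)
    return spec, vol, labels, mask


@pytest.fixture(scope="session")
def control_phantom():
    spec = PhantomSpec(seed=7)
    vol, labels, mask = generate_phantom(spec)
    return spec, vol, labels, mask


@pytest.fixture()
def flat_volume():
    """Synthetic constant-background volume with a uniform bright lesion,
    convenient for hand-computable contrast arithmetic."""
    data = np.ones((20, 20, 4))
    mask = np.ones_like(data, dtype=bool)
    lesion = np.zeros_like(data, dtype=np.int32)
    lesion[8:12, 8:12, 1:3] = 1
    data[lesion > 0] = 2.0
    return Volume(data, (1.0, 1.0, 5.0), mask), lesion
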