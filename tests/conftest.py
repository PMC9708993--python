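import numpy as np
import pytest

from ggnforge.phantom import PhantomConfig, make_phantom_dataset
from ggnforge.preprocess import blank_roi, normalize_intensity

HU_WINDOW = (-1000.0, 400.0)


@pytest.fixture(scope="session")
def phantom_dataset():
    """Eight 64x64 phantom slices, all carrying a ground-glass lesion."""
    config = PhantomConfig(image_size=64)
    return make_phantom_dataset(8, 1.0, config, seed=5)


@pytest.fixture(scope="session")
def training_pairs(phantom_dataset):
    """Normalised training pairs with a 16-pixel ROI blanked."""
    return [
        blank_roi(normalize_intensity(sl, HU_WINDOW), anns[0], 16)
        for sl, anns, _lung in phantom_dataset
    ]


@pytest.fixture(scope="session")
def lesion_slice(phantom_dataset):
    """One phantom slice plus the bounding-box mask of its lesion."""
    sl, anns, _lung = phantom_dataset[0]
    mask = np.zeros(sl.shape, dtype=bool)
    r0, c0, r1, c1 = anns[0].bbox
    mask[r0:r1, c0:c1] = True
    return sl, mask
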