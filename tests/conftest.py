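import numpy as np
import pytest
from hypothesis import settings

from lipodrop.segmentation import SegmentationParams
from lipodrop.synthetic import FieldSpec, generate_field

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def small_field():
    """One small noisy field with ground truth, shared across tests."""
    spec = FieldSpec(seed=11, n_cells=2, width_px=768, height_px=384,
                     ld_count_per_cell=60.0, snr=8.0)
    image, gt = generate_field(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def noiseless_field():
    """Blur-free, noise-free field: rendered channels are exact masks."""
    spec = FieldSpec(seed=12, n_cells=2, width_px=768, height_px=384,
                     ld_count_per_cell=40.0, snr=np.inf, psf_sigma_px=0.0)
    image, gt = generate_field(spec)
    return spec, image, gt


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
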