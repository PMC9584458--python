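import numpy as np
import pytest
from hypothesis import settings

import holowbc as h

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_optics() -> h.OpticalConfig:
    """Desk-scale SLM (68 x 120) with the bench's physical constants."""
    return h.OpticalConfig(slm_shape=(68, 120))


@pytest.fixture(scope="session")
def lymph_scene() -> h.SyntheticScene:
    """Noiseless single-lymphocyte scene with exact ground truth."""
    spec = h.CellSpec.for_kind("lymphocyte", center=(128, 128))
    return h.render_scene([spec], size=(256, 256), noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def scaled_seg_cfg() -> h.SegmentationConfig:
    """Segmentation config rescaled for the 256 px fixtures (min area 500 px)."""
    return h.SegmentationConfig().rescaled(0.1)


def wbc_amplitude(kind: str, slm_shape: tuple[int, int], scale: float = 0.35,
                  cancer: bool = False, seed: int = 3) -> np.ndarray:
    """Segmented-cell amplitude (inverted stain inside the mask) on an SLM frame."""
    spec = h.CellSpec.for_kind(kind, center=(slm_shape[0] / 2, slm_shape[1] / 2),
                               scale=scale, cancer=cancer)
    scene = h.render_scene([spec], size=slm_shape, noise_sigma=0.0, seed=seed)
    seg = h.segment_wbc(scene.image, h.SegmentationConfig().rescaled(0.05))
    return (1.0 - seg.green_enhanced) * seg.cell_mask
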