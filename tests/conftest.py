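import numpy as np
import pytest

from phccsurv.preprocess import PatchGridConfig, extract_patch_pairs
from phccsurv.synthetic import SlideGenParams, generate_slide


@pytest.fixture(scope="session")
def grid32() -> PatchGridConfig:
    return PatchGridConfig(patch_px=32, focus_mag=20, context_mag=5)


@pytest.fixture(scope="session")
def small_slides():
    """Eight 128x128 slides with strong tumor texture and some background."""
    return {
        f"s{i}": generate_slide(
            SlideGenParams(
                width_px=128,
                height_px=128,
                tumor_fraction=0.3,
                background_fraction=0.25,
                texture_contrast=0.7,
                seed=100 + i,
            )
        )
        for i in range(8)
    }


@pytest.fixture(scope="session")
def small_pairs(small_slides, grid32):
    return {
        sid: extract_patch_pairs(s, grid32, slide_id=sid)
        for sid, s in small_slides.items()
    }
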