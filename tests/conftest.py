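import dataclasses

import numpy as np
import pytest

from nodtex.phantom import (
    NoduleSpec,
    PhantomScene,
    RenderConfig,
    ScanProtocol,
    render_phantom,
)
from nodtex.texture import QuantizedROI


NOISE_FREE = dataclasses.replace(RenderConfig(), noise_scale=0.0, texture_sd_hu=0.0)


def make_roi(gray_volume: np.ndarray, mask: np.ndarray | None = None) -> QuantizedROI:
    """QuantizedROI directly from gray levels (bypasses HU quantization)."""
    g = np.asarray(gray_volume, dtype=np.int16)
    if mask is None:
        mask = g >= 0
    else:
        mask = np.asarray(mask, dtype=bool)
        g = np.where(mask, g, -1).astype(np.int16)
    return QuantizedROI(gray_volume=g, mask=mask)


def single_nodule_scene(
    diameter_mm: float = 12.0, target_hu: float = 100.0, fov: float = 30.0
) -> PhantomScene:
    c = fov / 2.0
    return PhantomScene(
        nodules=[NoduleSpec(diameter_mm, target_hu, (c, c, c))],
        field_of_view_mm=(fov, fov, fov),
    )


@pytest.fixture(scope="session")
def clean_nodule():
    """Noise-free, texture-free 12 mm / +100 HU nodule at 1.25 mm slices."""
    scene = single_nodule_scene()
    volume, masks = render_phantom(scene, ScanProtocol(1.25, 120, "standard"), seed=0, config=NOISE_FREE)
    return scene, volume, masks[0]
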