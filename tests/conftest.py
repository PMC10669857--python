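import numpy as np
import pytest

from endoqa.io_coco import Box
from endoqa.synthetic import DetectorNoise, SceneSpec, generate_scene, simulate_detections


@pytest.fixture
def disk_frame():
    """512x512 black frame with a bright disk of radius 200 at the center."""
    img = np.zeros((512, 512, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0:512, 0:512]
    disk = (xx - 255.5) ** 2 + (yy - 255.5) ** 2 <= 200**2
    img[disk] = 180
    return img, disk


@pytest.fixture
def small_scene():
    return generate_scene(SceneSpec(size=256, area_budget=0.15, seed=11))


@pytest.fixture
def oracle_scenes():
    """A batch of scenes with perfect (oracle) detections."""
    scenes = [
        generate_scene(SceneSpec(size=256, area_budget=0.12, seed=100 + i))
        for i in range(10)
    ]
    dets = [simulate_detections(s, DetectorNoise.oracle()) for s in scenes]
    return scenes, dets


def random_boxes(rng, n, extent=100, integer=False, label="blur", confidence=None):
    """n random valid boxes inside a square extent."""
    out = []
    for _ in range(n):
        if integer:
            x0, y0 = rng.integers(0, extent - 2, size=2)
            x1 = rng.integers(x0 + 1, extent)
            y1 = rng.integers(y0 + 1, extent)
        else:
            x0, y0 = rng.uniform(0, extent - 2, size=2)
            x1 = rng.uniform(x0 + 0.5, extent)
            y1 = rng.uniform(y0 + 0.5, extent)
        conf = float(rng.uniform(0.1, 1.0)) if confidence == "random" else confidence
        out.append(Box(float(x0), float(y0), float(x1), float(y1), label=label, confidence=conf))
    return out
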