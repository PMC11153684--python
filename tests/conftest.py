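"""Shared fixtures: phantoms and derived pipeline artifacts (session-cached)."""
import numpy as np
import pytest

from lungmet.io import VolumeImage
from lungmet.phantom import PhantomSpec, VesselTreeSpec, generate_phantom, _capsule_mask
from lungmet.segmentation import LungMask


@pytest.fixture(scope="session")
def phantom_default():
    """Default 64^3 phantom (noisy) with ground truth."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free 64^3 phantom for segmentation accuracy checks."""
    return generate_phantom(PhantomSpec(seed=1, noise_sd=0.0))


def vessels_only_volume(segments, shape=(64, 64, 64)):
    """Volume containing only a vessel tree on background, with an all-true mask.

    Isolates the vascular component so vessel detection can be tested without
    lung-boundary interference.
    """
    data = np.full(shape, 0.1)
    for s in segments:
        data[_capsule_mask(shape, (1.0, 1.0, 1.0), s.sl, s.el, s.r)] = 0.7
    return VolumeImage(data), LungMask(np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def separated_tree_phantom():
    """Depth-3 binary tree with widely separated branches (7 segments)."""
    spec = PhantomSpec(
        seed=5,
        noise_sd=0.0,
        n_metastases=0,
        vessel_tree=VesselTreeSpec(
            root_start=(16.0, 32.0, 14.0),
            root_h=16.0,
            root_radius=2.0,
            depth=3,
            height_decay=0.85,
            branch_angle_range=(0.7, 0.9),
        ),
    )
    return generate_phantom(spec)
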