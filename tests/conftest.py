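import numpy as np
import pytest

import fishbeat as fb

SMALL = (128, 128)
MEDIUM = (256, 256)


@pytest.fixture(scope="session")
def single_chamber_scene():
    """A noiseless one-chamber scene at an exact FFT bin (2.0 Hz, 13 fps)."""
    spec = fb.default_scene(seed=101, freq_hz=2.0, image_size=MEDIUM)
    stack, manifest = fb.render_scene(spec)
    return spec, stack, manifest


@pytest.fixture(scope="session")
def two_chamber_scene():
    """Two counter-beating chambers (phases 0.4 and 0.4 + pi) at 2.0 Hz."""
    spec = fb.default_scene(
        seed=202,
        freq_hz=2.0,
        image_size=MEDIUM,
        two_chambers=True,
        chamber_phases=(0.4, 0.4 + np.pi),
    )
    stack, manifest = fb.render_scene(spec)
    return spec, stack, manifest


@pytest.fixture(scope="session")
def small_scene_stack():
    """A fast 128x128 scene for plumbing-level tests."""
    spec = fb.default_scene(seed=7, freq_hz=2.0, image_size=SMALL)
    stack, manifest = fb.render_scene(spec)
    return stack, manifest


def constant_stack(n_frames=20, shape=(32, 32), value=0.5, fps=13.0):
    return fb.FrameStack(frames=np.full((n_frames, *shape), value), fps=fps)
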