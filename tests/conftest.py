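import numpy as np
import pytest

from reflexloc.data_io import EventAnnotation, FrameClip
from reflexloc.synthetic import SceneConfig, generate_clip


@pytest.fixture
def annotation():
    """An event [30, 36) in a 64-frame clip at 15 fps."""
    return EventAnnotation(
        clip_id="c1", participant_id="p1",
        start_frame=30, end_frame_exclusive=36, fps=15.0,
    )


@pytest.fixture
def gradient_clip():
    """A tiny deterministic clip whose frame t has constant value t/100."""
    frames = np.zeros((64, 8, 8, 3), dtype=np.float32)
    frames += (np.arange(64, dtype=np.float32) / 100.0)[:, None, None, None]
    return FrameClip(clip_id="c1", frames=frames, fps=15.0)


@pytest.fixture(scope="session")
def synthetic_clip():
    """One default-scene synthetic clip with its exact annotation."""
    clip, anns = generate_clip(SceneConfig(seed=11), clip_id="syn0",
                               participant_id="p0")
    return clip, anns[0]
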