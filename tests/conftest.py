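import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def graph():
    from spa_pta.skeleton_graph import build_graph

    return build_graph()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_coco_frame(rng=None, base=100.0):
    """One 17-keypoint frame as a flat AlphaPose-style keypoint list."""
    from spa_pta.pose_features import COCO_KEYPOINTS

    vals = []
    for k, _ in enumerate(COCO_KEYPOINTS):
        x = base + 10.0 * k
        y = base + 5.0 * k
        c = 0.9
        vals += [x, y, c]
    return vals
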