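import numpy as np
import pytest

from toolpose import (
    FrameAnnotation,
    Keypoint,
    Role,
    SceneConfig,
    ToolPose,
    Visibility,
)

VIS = Visibility.VISIBLE
OCC = Visibility.OCCLUDED


def kp(x, y, role, tag=VIS):
    return Keypoint(x, y, role, tag)


def make_pose(entry=(150.0, 250.0), hinge=(400.0, 260.0),
              tip1=(460.0, 230.0), tip2=(465.0, 300.0),
              tags=(VIS, VIS, VIS, VIS), instance_id=1):
    """Build a pose from coordinates and per-slot visibility tags."""
    roles = (Role.ENTRY, Role.HINGE, Role.TIP1, Role.TIP2)
    coords = (entry, hinge, tip1, tip2)
    slots = {}
    for name, xy, role, tag in zip(("entry", "hinge", "tip1", "tip2"),
                                   coords, roles, tags):
        if tag is Visibility.MISSING:
            slots[name] = Keypoint.missing(role)
        else:
            slots[name] = Keypoint(xy[0], xy[1], role, tag)
    return ToolPose(instance_id=instance_id, **slots)


@pytest.fixture
def pose():
    return make_pose()


@pytest.fixture
def frame(pose):
    return FrameAnnotation(frame_id="fixture", poses=[pose])


@pytest.fixture
def scene_config():
    return SceneConfig(seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
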