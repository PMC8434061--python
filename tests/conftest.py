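import numpy as np
import pytest

from microbehavior import (
    AnnotationTrack,
    FaceTrack,
    SyntheticConfig,
    generate_participant,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_track(
    n_frames: int = 64,
    frame_rate: float = 30.0,
    participant_id: str = "p1",
    rng: np.random.Generator | None = None,
) -> FaceTrack:
    """A small hand-built track: flat face, optional landmark jitter."""
    rng = rng or np.random.default_rng(0)
    timestamps = np.arange(n_frames) / frame_rate
    pose = rng.normal(0, 0.01, size=(n_frames, 3))
    landmarks = np.tile(
        np.column_stack([np.linspace(0, 67, 68), np.linspace(100, 167, 68)]),
        (n_frames, 1, 1),
    )
    return FaceTrack(participant_id, frame_rate, timestamps, pose, landmarks)


@pytest.fixture()
def small_track():
    return make_track()


@pytest.fixture()
def annotated_pair():
    """64-frame track at 30 fps with one speaking and one nodding interval."""
    track = make_track(n_frames=64)
    ann = AnnotationTrack(
        "p1", [("speaking", 0.2, 1.0), ("nodding", 1.5, 1.9)]
    )
    return track, ann


@pytest.fixture(scope="session")
def synthetic_pair():
    """One deterministic synthetic participant (60 s, enough events)."""
    cfg = SyntheticConfig(n_participants=1, duration=60.0, seed=99)
    return generate_participant(cfg, "p1", seed=99)
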