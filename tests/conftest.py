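import numpy as np
import pytest

from rbcflow.classify import ClassifierConfig, train_classifier
from rbcflow.detect import detect_sequence
from rbcflow.geometry import ChannelGeometry
from rbcflow.synth import get_preset, generate_sequence, make_labeled_crops
from rbcflow.track import build_tracks


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def moments_model():
    """Feature-based classifier trained on a modest balanced crop set."""
    crops, labels = make_labeled_crops(120, seed=7)
    return train_classifier(crops, labels, ClassifierConfig(backend="moments", seed=0))


@pytest.fixture(scope="session")
def control_run(geometry):
    """A 60-cell control sequence with its detections and tracks, shared
    across detection/tracking tests."""
    config = get_preset("control", cells_per_sequence=60, seed=5)
    frames, truth = generate_sequence(geometry, config)
    per_frame, background = detect_sequence(frames)
    tracks = build_tracks(per_frame, geometry, config.frame_rate_hz)
    return {
        "config": config,
        "frames": frames,
        "truth": truth,
        "per_frame": per_frame,
        "background": background,
        "tracks": tracks,
    }
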