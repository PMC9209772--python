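import numpy as np
import pytest

from semgnet import SimSpec, simulate_dataset
from semgnet.io import GestureEvent, Recording
from semgnet.pipeline import make_window_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_recording(rng, n_samples=500, n_channels=4, n_events=2):
    """Small seeded recording with valid non-overlapping events."""
    events = []
    span = n_samples // max(n_events, 1)
    for i in range(n_events):
        a = i * span + 10
        b = a + span // 2
        events.append(GestureEvent(gesture_id=i + 1, onset_sample=a,
                                   offset_sample=b, repetition=0))
    return Recording(
        semg=rng.standard_normal((n_samples, n_channels)),
        acc=rng.standard_normal((n_samples, 3)) * 0.1,
        fs=1000.0,
        channel_ids=tuple(range(1, n_channels + 1)),
        events=events,
    )


@pytest.fixture
def small_recording(rng):
    return random_recording(rng)


@pytest.fixture(scope="session")
def easy_window_data():
    """Windowed train/test arrays from the well-separated 5-class spec.

    Session-scoped: simulation + filtering is shared across the network and
    acceptance tests that train on it.
    """
    spec = SimSpec.easy(seed=0)
    train_recs, test_recs = simulate_dataset(spec)
    train, test, stats = make_window_dataset(train_recs, test_recs)
    return {"spec": spec, "train": train, "test": test, "stats": stats}


def stratified_subset(y, per_class, offset=0):
    """Indices picking `per_class` windows of every class (deterministic)."""
    idx = []
    for k in np.unique(y):
        where = np.where(y == k)[0]
        idx.append(where[offset : offset + per_class])
    return np.sort(np.concatenate(idx))
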