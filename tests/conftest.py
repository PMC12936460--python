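import numpy as np
import pytest

from fedpneu import (
    LabelledDataset,
    SynthSpec,
    generate_dataset,
    normalize_pixels,
    split_train_test,
)

STUDY_SPEC = SynthSpec(
    n_images=600,
    image_size=(28, 28),
    channels=1,
    prevalence=0.5,
    opacity_intensity=120.0,
    noise_sd=20.0,
    seed=7,
)


@pytest.fixture(scope="session")
def study_pair():
    """Normalized 90:10 split of the standard synthetic study dataset (n=600)."""
    return split_train_test(normalize_pixels(generate_dataset(STUDY_SPEC)), 0.9, 42)


@pytest.fixture(scope="session")
def small_pair():
    """A small, clearly separable dataset for fast training tests (n=200)."""
    spec = SynthSpec(n_images=200, image_size=(12, 12), opacity_radius_px=3.0,
                     opacity_intensity=120.0, noise_sd=10.0, seed=3)
    return split_train_test(normalize_pixels(generate_dataset(spec)), 0.9, 42)


def id_dataset(n: int, n_pos: int | None = None) -> LabelledDataset:
    """Tiny dataset whose single pixel encodes the sample index, for tracking
    samples through shuffles, splits and shards."""
    if n_pos is None:
        n_pos = n // 2
    images = np.arange(n, dtype=np.float64).reshape(n, 1, 1, 1)
    onehot = np.zeros((n, 2))
    onehot[:n_pos, 1] = 1.0
    onehot[n_pos:, 0] = 1.0
    return LabelledDataset(images, onehot, ("normal", "pneumonia"))


def sample_ids(dataset: LabelledDataset) -> set[int]:
    return set(np.asarray(dataset.images).reshape(-1).astype(int))


def threshold_baseline_accuracy(pair) -> float:
    """Independent one-parameter oracle: mean-pixel threshold classifier.

    The cut point is tuned on the training split by exhaustive search over
    the observed means, then evaluated on the held-out split.
    """
    means_tr = pair.train.images.reshape(len(pair.train), -1).mean(axis=1)
    y_tr = np.argmax(pair.train.labels_onehot, axis=1)
    best_thr = max(np.unique(means_tr), key=lambda t: ((means_tr > t) == y_tr).mean())
    means_te = pair.test.images.reshape(len(pair.test), -1).mean(axis=1)
    y_te = np.argmax(pair.test.labels_onehot, axis=1)
    return float(((means_te > best_thr) == y_te).mean())
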