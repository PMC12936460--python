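"""Image loading, normalization, label encoding and train/test splitting.

The pipeline mirrors the standard Kaggle chest-X-ray workflow: images live
in class-named subdirectories, are resized to a fixed shape, scaled from
8-bit intensities into [0, 1], label-binarized into one-hot rows, and split
into a 90:10 train/test pair under a fixed shuffle seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: supported raster extensions, lower-case
_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class LabelledDataset:
    """A stack of same-shape images with one-hot labels.

    ``images`` has shape ``(N, H, W, C)``.  Values are 8-bit intensities in
    [0, 255] straight after loading or generation, and floats in [0, 1]
    after :func:`normalize_pixels`.  ``labels_onehot`` has one unit row per
    image over the ordered ``class_names`` vocabulary.
    """

    images: np.ndarray
    labels_onehot: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels_onehot = np.asarray(self.labels_onehot, dtype=np.float64)
        self.class_names = tuple(self.class_names)
        if self.images.ndim != 4:
            raise ValueError(
                f"images must be a (N, H, W, C) array, got ndim={self.images.ndim}"
            )
        if self.labels_onehot.ndim != 2:
            raise ValueError("labels_onehot must be a 2-D matrix")
        if len(self.images) != len(self.labels_onehot):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels_onehot)} label rows"
            )
        if self.labels_onehot.shape[1] != len(self.class_names):
            raise ValueError("one-hot width must equal the vocabulary size")
        rows = self.labels_onehot.sum(axis=1)
        if len(rows) and not np.array_equal(rows, np.ones_like(rows)):
            raise ValueError("every one-hot row must sum to exactly 1")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> list[str]:
        """Class names decoded from the one-hot rows."""
        return one_hot_decode(self.labels_onehot, self.class_names)

    def class_counts(self) -> dict[str, int]:
        counts = self.labels_onehot.sum(axis=0)
        return {name: int(c) for name, c in zip(self.class_names, counts)}

    def subset(self, indices: np.ndarray) -> "LabelledDataset":
        """A new dataset holding the given samples, in the given order."""
        idx = np.asarray(indices)
        return LabelledDataset(
            images=self.images[idx],
            labels_onehot=self.labels_onehot[idx],
            class_names=self.class_names,
        )


@dataclass
class SplitPair:
    """A disjoint train/test partition of one dataset."""

    train: LabelledDataset
    test: LabelledDataset
    ratio: float
    seed: int


def load_image_dir(
    root_path: str | Path,
    image_size: tuple[int, int] = (28, 28),
    channels: int = 1,
) -> LabelledDataset:
    """Load a class-per-subdirectory image tree into a dataset.

    Every decodable image under ``<root>/<CLASS>/`` is resized to
    ``image_size`` (bilinear) with the requested channel count; pixel
    values stay on the 0-255 scale.  Labels come from the subdirectory
    names (lower-cased); files are visited in lexicographic path order so
    the dataset is reproducible across filesystems.  Undecodable files are
    skipped with a warning.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"image root {root} is not a directory")
    if channels not in (1, 3):
        raise ValueError(f"channels must be 1 or 3, got {channels}")
    h, w = image_size

    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    class_names = tuple(d.name.lower() for d in class_dirs)

    images: list[np.ndarray] = []
    labels: list[str] = []
    n_skipped = 0
    for class_dir, class_name in zip(class_dirs, class_names):
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in _IMAGE_EXTENSIONS or not path.is_file():
                continue
            try:
                with Image.open(path) as img:
                    img = img.convert("L" if channels == 1 else "RGB")
                    if img.size != (w, h):  # PIL size is (width, height)
                        img = img.resize((w, h), resample=Image.BILINEAR)
                    arr = np.asarray(img, dtype=np.uint8)
            except (UnidentifiedImageError, OSError) as exc:
                n_skipped += 1
                logger.warning("skipping undecodable image %s: %s", path, exc)
                continue
            if channels == 1:
                arr = arr[:, :, np.newaxis]
            images.append(arr)
            labels.append(class_name)
    if n_skipped:
        logger.warning("skipped %d undecodable file(s) under %s", n_skipped, root)
    if not images:
        raise ValueError(f"no decodable images found under {root}")

    return LabelledDataset(
        images=np.stack(images),
        labels_onehot=one_hot_encode(labels, class_names),
        class_names=class_names,
    )


def normalize_pixels(dataset: LabelledDataset) -> LabelledDataset:
    """Scale 8-bit intensities into [0, 1] by dividing by 255.

    The input must hold integer-valued pixels in [0, 255]; anything else
    (e.g. data that was already normalized) is rejected, naming the first
    offending index.  An all-{0, 1} input — possibly a binary mask — is
    accepted with a logged warning.
    """
    px = np.asarray(dataset.images, dtype=np.float64)
    bad = ~np.isfinite(px) | (px < 0) | (px > 255) | (px != np.floor(px))
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"pixel at index {idx} has value {px[idx]!r}; normalize_pixels "
            "requires integer values in [0, 255] (is the data already normalized?)"
        )
    if px.size and np.isin(px, (0.0, 1.0)).all():
        logger.warning(
            "all pixel values are 0/1; treating input as a binary mask on the "
            "0-255 scale and dividing by 255 anyway"
        )
    return LabelledDataset(
        images=px / 255.0,
        labels_onehot=dataset.labels_onehot,
        class_names=dataset.class_names,
    )


def one_hot_encode(labels, class_names) -> np.ndarray:
    """Encode class names as unit rows over the ``class_names`` vocabulary."""
    vocab = {name: i for i, name in enumerate(class_names)}
    out = np.zeros((len(labels), len(class_names)), dtype=np.float64)
    for row, label in enumerate(labels):
        if label not in vocab:
            raise ValueError(
                f"label {label!r} not in class vocabulary {tuple(class_names)}"
            )
        out[row, vocab[label]] = 1.0
    return out


def one_hot_decode(matrix: np.ndarray, class_names) -> list[str]:
    """Invert :func:`one_hot_encode`."""
    matrix = np.asarray(matrix)
    return [class_names[j] for j in np.argmax(matrix, axis=1)]


def split_train_test(
    dataset: LabelledDataset, ratio: float = 0.9, seed: int = 42
) -> SplitPair:
    """Shuffle then split a dataset into train/test at ``ratio``.

    ``ratio`` is the train fraction; the split is delegated to
    scikit-learn's ``train_test_split`` with ``random_state=seed``, so the
    same (dataset, ratio, seed) triple always yields the same partition.
    """
    n = len(dataset)
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must lie in (0, 1), got {ratio}")
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    # integer test count keeps both sides non-empty at extreme ratios
    n_test = min(max(n - round(ratio * n), 1), n - 1)
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=n_test, random_state=seed, shuffle=True
    )
    return SplitPair(
        train=dataset.subset(train_idx),
        test=dataset.subset(test_idx),
        ratio=ratio,
        seed=seed,
    )


def write_manifest(dataset: LabelledDataset, paths, split_names, out_path) -> None:
    """Write an audit manifest CSV with columns ``path,class,split``."""
    import pandas as pd

    pd.DataFrame(
        {"path": list(paths), "class": dataset.labels, "split": list(split_names)}
    ).to_csv(out_path, index=False)
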