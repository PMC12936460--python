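"""Synthetic two-class chest-X-ray-like image generator.

Real pneumonia radiographs show bright consolidation opacities inside a
darker lung field.  The generator emulates only that separating feature:
both classes share a fixed low-intensity vignette background (darker
borders, brighter centre) plus per-pixel Gaussian noise, and the positive
("pneumonia") class additionally carries one filled elliptical patch with a
Gaussian-feathered edge, centred uniformly at random within the central
lung-field region.  Class separability is therefore controlled entirely by
the patch intensity relative to the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data import LabelledDataset, one_hot_encode

CLASS_NAMES = ("normal", "pneumonia")

# background vignette intensity range on the 0-255 scale, shared by both classes
_BG_BORDER = 20.0
_BG_CENTRE = 100.0


@dataclass
class SynthSpec:
    """Generation parameters for one synthetic dataset.

    Parameters
    ----------
    n_images : total sample count (>= 2).
    image_size : (height, width) in pixels.
    channels : 1 for grayscale, 3 replicates the channel.
    prevalence : fraction of positive ("pneumonia") samples, in [0, 1].
    opacity_intensity : mean added brightness of the patch, 0-255 scale.
    opacity_radius_px : patch semi-major radius in pixels; must fit inside
        the image (< min(image_size)/2).
    noise_sd : per-pixel Gaussian noise standard deviation, 0-255 scale.
    seed : RNG seed; identical specs produce byte-identical images.
    """

    n_images: int = 600
    image_size: tuple[int, int] = (28, 28)
    channels: int = 1
    prevalence: float = 0.5
    opacity_intensity: float = 120.0
    opacity_radius_px: float = 5.0
    noise_sd: float = 20.0
    seed: int = 7

    def __post_init__(self) -> None:
        if int(self.n_images) != self.n_images or self.n_images < 2:
            raise ValueError(f"n_images must be an integer >= 2, got {self.n_images}")
        if len(self.image_size) != 2 or min(self.image_size) < 1:
            raise ValueError(f"image_size must be positive (h, w), got {self.image_size}")
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if not 0.0 <= self.opacity_intensity <= 255.0:
            raise ValueError(
                f"opacity_intensity must lie in [0, 255], got {self.opacity_intensity}"
            )
        if not 0 < self.opacity_radius_px < min(self.image_size) / 2:
            raise ValueError(
                f"opacity_radius_px must lie in (0, {min(self.image_size) / 2}) "
                f"for image_size {self.image_size}, got {self.opacity_radius_px}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")


def _background(h: int, w: int) -> np.ndarray:
    """Fixed vignette: brighter centre, darker borders. Shared by both classes."""
    yy = (np.arange(h) - (h - 1) / 2) / (h / 2)
    xx = (np.arange(w) - (w - 1) / 2) / (w / 2)
    d2 = yy[:, None] ** 2 + xx[None, :] ** 2
    return _BG_BORDER + (_BG_CENTRE - _BG_BORDER) * np.clip(1.0 - d2 / 2.0, 0.0, 1.0)


def _opacity_patch(
    h: int, w: int, spec: SynthSpec, rng: np.random.Generator
) -> np.ndarray:
    """One feathered elliptical opacity, centred in the central lung-field region.

    The added-brightness field is rescaled so its mean over the ellipse
    support equals ``opacity_intensity``.
    """
    # centre uniform within the central half of each dimension
    cy = rng.uniform(0.25 * h, 0.75 * h)
    cx = rng.uniform(0.25 * w, 0.75 * w)
    ry = spec.opacity_radius_px
    rx = spec.opacity_radius_px * rng.uniform(0.6, 1.0)

    yy = (np.arange(h)[:, None] - cy) / ry
    xx = (np.arange(w)[None, :] - cx) / rx
    d2 = yy**2 + xx**2
    support = d2 < 1.0
    profile = np.where(support, np.exp(-3.0 * d2), 0.0)  # Gaussian-feathered edge
    mean_in_support = profile[support].mean()
    return spec.opacity_intensity / mean_in_support * profile


def generate_dataset(spec: SynthSpec) -> LabelledDataset:
    """Generate ``spec.n_images`` labelled 8-bit images (values 0-255).

    Exactly ``round(prevalence * n_images)`` samples carry the "pneumonia"
    label and one bright patch; the rest are background + noise only.
    Deterministic in the spec, including byte-identical pixels.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n = int(spec.n_images)
    n_pos = int(round(spec.prevalence * n))

    labels = np.array([CLASS_NAMES[1]] * n_pos + [CLASS_NAMES[0]] * (n - n_pos))
    rng.shuffle(labels)

    bg = _background(h, w)
    images = np.empty((n, h, w, spec.channels), dtype=np.uint8)
    for i, label in enumerate(labels):
        field = bg + rng.normal(0.0, spec.noise_sd, size=(h, w))
        if label == CLASS_NAMES[1]:
            field = field + _opacity_patch(h, w, spec, rng)
        pixel = np.clip(np.rint(field), 0, 255).astype(np.uint8)
        images[i] = np.repeat(pixel[:, :, None], spec.channels, axis=2)

    return LabelledDataset(
        images=images,
        labels_onehot=one_hot_encode(labels, CLASS_NAMES),
        class_names=CLASS_NAMES,
    )


def write_image_dir(dataset: LabelledDataset, root_path: str | Path) -> list[Path]:
    """Write one 8-bit PNG per sample under per-class subdirectories.

    The layout is the Kaggle chest-X-ray convention
    ``<root>/<CLASS_NAME>/<index>.png`` with upper-case class directories.
    PNG is lossless, so re-loading the tree reproduces pixels and labels
    exactly.  Returns the written paths.
    """
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    images = np.asarray(dataset.images)
    if images.dtype != np.uint8:
        if ((images < 0) | (images > 255) | (images != np.floor(images))).any():
            raise ValueError("pixel values must be 8-bit integers in [0, 255]")
        images = images.astype(np.uint8)

    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    for name in dataset.class_names:
        (root / name.upper()).mkdir(exist_ok=True)

    paths: list[Path] = []
    for i, (pixels, label) in enumerate(zip(images, dataset.labels)):
        path = root / label.upper() / f"{i:05d}.png"
        arr = pixels[:, :, 0] if pixels.shape[2] == 1 else pixels
        Image.fromarray(arr).save(path, format="PNG")
        paths.append(path)
    return paths
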