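"""Uniform sizing, quarter-turn rotations, augmentation and the rotation-pretext dataset.

The pretext task follows the rotation-prediction recipe: every image is
expanded into its four clockwise quarter-turns, labeled 0-3 by the number of
turns. Quarter-turns are pure index permutations (lossless), which is also why
training-time "random rotation" augmentation defaults to quarter-turns rather
than arbitrary-angle interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["RotationSample", "resize_or_pad", "rotate_quarter", "build_rotation_dataset", "augment"]


@dataclass
class RotationSample:
    pixel_data: np.ndarray
    rotation_label: int  # number of clockwise quarter-turns applied
    source_image_id: str

    def __post_init__(self) -> None:
        if self.rotation_label not in (0, 1, 2, 3):
            raise ValueError(f"rotation_label must be in 0..3, got {self.rotation_label}")


def _to_3ch(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape[2] == 1:
        image = np.repeat(image, 3, axis=2)
    if image.shape[2] != 3:
        raise ValueError(f"channel count must be 1 or 3, got {image.shape[2]}")
    return image


def resize_or_pad(image: np.ndarray, target_edge: int, mode: str = "resize") -> np.ndarray:
    """Bring an image to ``target_edge x target_edge x 3``.

    ``pad`` centers the image on a zero background and requires both edges
    <= target. ``resize`` rescales (bilinear, aspect preserved, long edge to
    target) then center-pads the short edge. Single-channel input is
    replicated to three channels.
    """
    if target_edge < 8:
        raise ValueError("target_edge must be >= 8")
    image = _to_3ch(np.asarray(image))
    h, w = image.shape[:2]
    if mode == "pad":
        if h > target_edge or w > target_edge:
            raise ValueError(
                f"pad mode needs both edges <= {target_edge}, got {h}x{w}; use mode='resize'"
            )
    elif mode == "resize":
        if max(h, w) != target_edge:
            scale = target_edge / max(h, w)
            nh = min(target_edge, max(1, int(round(h * scale))))
            nw = min(target_edge, max(1, int(round(w * scale))))
            image = _sk_resize(
                image, (nh, nw), order=1, anti_aliasing=scale < 1.0, preserve_range=True
            ).astype(np.float32)
            h, w = nh, nw
    else:
        raise ValueError(f"mode must be 'resize' or 'pad', got {mode!r}")
    out = np.zeros((target_edge, target_edge, 3), dtype=np.float32)
    top = (target_edge - h) // 2
    left = (target_edge - w) // 2
    out[top : top + h, left : left + w, :] = image
    return out


def rotate_quarter(image: np.ndarray, k: int) -> np.ndarray:
    """Exact clockwise rotation by ``k`` quarter-turns (index permutation)."""
    image = np.asarray(image)
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"rotate_quarter requires a square image, got {image.shape[:2]}")
    if k not in (0, 1, 2, 3):
        raise ValueError(f"k must be in 0..3, got {k}")
    return np.rot90(image, k=-k, axes=(0, 1)).copy()


def build_rotation_dataset(images: list[np.ndarray], image_ids: list[str] | None = None) -> list[RotationSample]:
    """Expand each square image into its four rotations, labeled 0-3.

    Grade labels are deliberately not carried over: the pretext task must not
    reveal the grading semantics of its source images.
    """
    if image_ids is None:
        image_ids = [f"img{i}" for i in range(len(images))]
    samples = []
    for img, iid in zip(images, image_ids):
        for k in range(4):
            samples.append(RotationSample(rotate_quarter(img, k), k, iid))
    return samples


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation: a random quarter-turn plus a 50% horizontal flip.

    Both operations are pixel permutations, so the pixel multiset is preserved.
    Deterministic given the generator state.
    """
    out = rotate_quarter(image, int(rng.integers(4)))
    if rng.random() < 0.5:
        out = out[:, ::-1].copy()
    return out
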