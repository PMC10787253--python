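"""Seeded image augmentations and their named mix compositions.

Six augmentation families are supported — gaussian blur, right-angle
rotations and flips, contrast, saturation, brightness, and hue-shift —
plus three standard combinations: ``mix1`` (rotations/flips + blur),
``mix2`` (mix1 + brightness + contrast), and ``mix3`` (all six).

The hue-shift deserves a note: it rotates the hue of *every* pixel by the
same amount on the HSV colour wheel (wrap-around), which simulates tiles
prepared with different staining protocols while leaving saturation and
value untouched (to within 8-bit quantisation, ±1 channel unit).

All randomness flows from a single seeded generator, so a given
``(image, spec)`` pair produces bit-identical output on every run — a
requirement for reproducible dataset previews and training pipelines.

Default parameter ranges are conventional magnitudes and fully
configurable: blur sigma U(0,2) px; brightness/contrast/saturation factors
U(0.7,1.3); hue delta U(-0.1,0.1) turns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from .errors import ConfigurationError

OP_NAMES = (
    "gaussian_blur",
    "rotations_flips",
    "contrast",
    "saturation",
    "brightness",
    "hue_shift",
)

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "gaussian_blur": (0.0, 2.0),  # sigma, px
    "contrast": (0.7, 1.3),  # multiplicative factor
    "saturation": (0.7, 1.3),
    "brightness": (0.7, 1.3),
    "hue_shift": (-0.1, 0.1),  # hue turns
}


@dataclass(frozen=True)
class AugmentationSpec:
    """An ordered list of augmentation ops with parameter ranges and a seed."""

    ops: tuple[str, ...]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("ops must be non-empty")
        for op in self.ops:
            if op not in OP_NAMES:
                raise ConfigurationError(
                    f"unknown augmentation op {op!r}; known: {OP_NAMES}"
                )
        merged = {**DEFAULT_RANGES, **self.ranges}
        lo, hi = merged["gaussian_blur"]
        if lo < 0:
            raise ValueError(f"blur sigma must be >= 0, got range {(lo, hi)}")
        lo, hi = merged["hue_shift"]
        if not (-0.5 < lo <= 0.5 and -0.5 < hi <= 0.5):
            raise ValueError(f"hue delta range must lie in (-0.5, 0.5], got {(lo, hi)}")
        object.__setattr__(self, "ops", tuple(self.ops))
        object.__setattr__(self, "ranges", merged)


def _as_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def hue_shift(image: np.ndarray, delta: float) -> np.ndarray:
    """Rotate every pixel's hue by ``delta`` turns (wrap-around).

    ``delta`` in turns of the HSV wheel, in (-0.5, 0.5]; 1/3 maps pure red
    onto pure green.  Saturation and value are preserved to within one
    8-bit quantisation step.
    """
    if not -0.5 < delta <= 0.5:
        raise ValueError(f"delta must be in (-0.5, 0.5], got {delta}")
    if delta == 0.0:
        return image.copy()
    hsv = rgb2hsv(image)
    hsv[:, :, 0] = (hsv[:, :, 0] + delta) % 1.0
    return _as_uint8(hsv2rgb(hsv) * 255.0)


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with the given sigma in pixels; sigma 0 is identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0.0:
        return image.copy()
    blurred = np.stack(
        [ndimage.gaussian_filter(image[:, :, c].astype(np.float64), sigma) for c in range(3)],
        axis=-1,
    )
    return _as_uint8(blurred)


def rotate_flip(image: np.ndarray, quarter_turns: int, flip_h: bool, flip_v: bool) -> np.ndarray:
    """Rotate by multiples of 90 degrees and optionally mirror.

    Pure pixel permutation: the multiset of pixel values is unchanged.
    """
    out = np.rot90(image, k=quarter_turns % 4)
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale all channels by ``factor`` (clipped to 8-bit range)."""
    return _as_uint8(image.astype(np.float64) * factor)


def adjust_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale deviation from the image's mean luminance by ``factor``."""
    img = image.astype(np.float64)
    mean = img.mean()
    return _as_uint8(mean + (img - mean) * factor)


def adjust_saturation(image: np.ndarray, factor: float) -> np.ndarray:
    """Blend between the grayscale (Rec.601 luma) and the original image."""
    img = image.astype(np.float64)
    gray = img @ np.array([0.299, 0.587, 0.114])
    gray3 = gray[:, :, None]
    return _as_uint8(gray3 + (img - gray3) * factor)


def compose_mix(name: str, seed: int = 0) -> AugmentationSpec:
    """Build one of the named augmentation combinations.

    ``mix1`` = rotations/flips + blur; ``mix2`` = mix1 + brightness +
    contrast; ``mix3`` = all six ops.
    """
    mixes = {
        "mix1": ("rotations_flips", "gaussian_blur"),
        "mix2": ("rotations_flips", "gaussian_blur", "brightness", "contrast"),
        "mix3": OP_NAMES,
    }
    if name not in mixes:
        raise ValueError(f"unknown mix {name!r}; known: {sorted(mixes)}")
    return AugmentationSpec(ops=mixes[name], seed=seed)


def apply_augmentation(image: np.ndarray, spec: AugmentationSpec) -> np.ndarray:
    """Apply the spec's ops in order, all randomness from the spec's seed.

    The same ``(image, spec)`` pair yields bit-identical output across
    runs.  For non-square images the random rotation is restricted to
    0/180 degrees so output dimensions always equal input dimensions.
    """
    img = np.asarray(image, dtype=np.uint8)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    rng = np.random.default_rng(spec.seed)
    for op in spec.ops:
        if op == "rotations_flips":
            choices = 4 if img.shape[0] == img.shape[1] else 2
            k = int(rng.integers(0, choices))
            if choices == 2:
                k *= 2  # 0 or 180 degrees only
            img = rotate_flip(img, k, bool(rng.integers(0, 2)), bool(rng.integers(0, 2)))
        elif op == "gaussian_blur":
            img = gaussian_blur(img, rng.uniform(*spec.ranges["gaussian_blur"]))
        elif op == "contrast":
            img = adjust_contrast(img, rng.uniform(*spec.ranges["contrast"]))
        elif op == "saturation":
            img = adjust_saturation(img, rng.uniform(*spec.ranges["saturation"]))
        elif op == "brightness":
            img = adjust_brightness(img, rng.uniform(*spec.ranges["brightness"]))
        elif op == "hue_shift":
            img = hue_shift(img, rng.uniform(*spec.ranges["hue_shift"]))
        else:  # unreachable: spec validates op names
            raise ConfigurationError(f"unknown augmentation op {op!r}")
    return img
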