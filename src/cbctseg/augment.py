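"""Training-time volumetric augmentation: crop, mirror flip, cutout masks.

Three ops, applied in a fixed order (crop, flip, mask) from one shared
random stream so that a single seed documents the whole transform:

* random crop of a 96 x 160 x 160 patch (image and labels share the window;
  undersized inputs are symmetrically padded first — image with its minimum
  value, labels with background);
* independent mirror flip of each axis with probability 0.5;
* cutout — 0 to 16 cubes of 12^3 voxels set to zero at uniform random
  positions (overlaps allowed, labels untouched).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CbctError, LabelVolume, Volume

__all__ = [
    "AugmentConfig",
    "random_crop",
    "random_flip",
    "random_mask",
    "augment_case",
]


@dataclass(frozen=True)
class AugmentConfig:
    crop_shape: tuple[int, int, int] = (96, 160, 160)
    mask_cube: int = 12
    mask_count_range: tuple[int, int] = (0, 16)
    flip_prob_per_axis: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.crop_shape):
            raise CbctError("crop_shape components must be >= 1")
        if self.mask_cube < 1:
            raise CbctError("mask_cube must be >= 1")
        lo, hi = self.mask_count_range
        if not 0 <= lo <= hi:
            raise CbctError("mask_count_range must satisfy 0 <= min <= max")
        if not 0.0 <= self.flip_prob_per_axis <= 1.0:
            raise CbctError("flip_prob_per_axis must be a probability")


def _pad_to(values: np.ndarray, shape, fill) -> np.ndarray:
    pads = []
    for dim, want in zip(values.shape, shape):
        extra = max(0, want - dim)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        values = np.pad(values, pads, mode="constant", constant_values=fill)
    return values


def random_crop(
    volume: Volume,
    labels: LabelVolume,
    shape: tuple[int, int, int] = (96, 160, 160),
    rng: np.random.Generator | None = None,
) -> tuple[Volume, LabelVolume]:
    """Crop the same random ``shape`` window from volume and labels.

    The window corner is uniform over all valid placements.  Inputs smaller
    than ``shape`` on any axis are symmetrically padded first.
    """
    volume.require_same_grid(labels)
    rng = rng if rng is not None else np.random.default_rng()
    vals = _pad_to(np.asarray(volume.values), shape, np.asarray(volume.values).min())
    labs = _pad_to(np.asarray(labels.values), shape, 0)
    corner = tuple(
        int(rng.integers(0, dim - want + 1)) for dim, want in zip(vals.shape, shape)
    )
    window = tuple(slice(c, c + want) for c, want in zip(corner, shape))
    return (
        Volume(vals[window].copy(), volume.spacing, volume.origin),
        LabelVolume(labs[window].copy(), labels.spacing, labels.origin),
    )


def random_flip(
    volume: Volume,
    labels: LabelVolume,
    rng: np.random.Generator | None = None,
    flip_prob_per_axis: float = 0.5,
) -> tuple[Volume, LabelVolume]:
    """Mirror each axis independently with ``flip_prob_per_axis``.

    The same axis draw is applied to image and labels, so the voxel multiset
    and per-class counts are preserved.
    """
    volume.require_same_grid(labels)
    rng = rng if rng is not None else np.random.default_rng()
    axes = tuple(int(a) for a in range(3) if rng.random() < flip_prob_per_axis)
    if not axes:
        return volume, labels
    return (
        volume.with_values(np.flip(volume.values, axes).copy()),
        LabelVolume(np.flip(labels.values, axes).copy(), labels.spacing, labels.origin),
    )


def random_mask(
    volume: Volume,
    config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
    count: int | None = None,
) -> Volume:
    """Zero out ``n`` random cubes of ``mask_cube``^3 voxels (cutout).

    ``n`` is uniform over ``mask_count_range`` unless ``count`` forces it.
    Cube corners are uniform over in-bounds positions; overlap is allowed, so
    at most ``n * mask_cube^3`` voxels are zeroed.  Labels are never touched
    by this op.
    """
    config = config or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng()
    cube = config.mask_cube
    if any(dim < cube for dim in volume.shape):
        raise CbctError(f"volume {volume.shape} smaller than mask cube {cube}")
    if count is None:
        lo, hi = config.mask_count_range
        count = int(rng.integers(lo, hi + 1))
    values = np.array(volume.values, copy=True)
    for _ in range(count):
        corner = tuple(int(rng.integers(0, dim - cube + 1)) for dim in volume.shape)
        values[tuple(slice(c, c + cube) for c in corner)] = 0
    return volume.with_values(values)


def augment_case(
    volume: Volume, labels: LabelVolume, config: AugmentConfig | None = None
) -> tuple[Volume, LabelVolume]:
    """Full pipeline: crop, flip, mask, from one seeded stream.

    Bit-identical across runs for fixed ``(input, config.seed)``.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    vol, lab = random_crop(volume, labels, config.crop_shape, rng)
    vol, lab = random_flip(vol, lab, rng, config.flip_prob_per_axis)
    vol = random_mask(vol, config, rng)
    return vol, lab
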