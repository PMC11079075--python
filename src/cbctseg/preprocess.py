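"""Image standardization: isotropic resampling, clipping, z-normalization.

The chain runs in a fixed order:

1. resample to isotropic 0.4 mm voxels (linear for images, nearest for
   labels);
2. determine the lower clip bound — adaptively via the histogram analysis
   of :mod:`cbctseg.histogram` (bone truncation value ``x_b``), or with the
   generic percentile baseline (0.5th percentile) used by most pipelines;
3. clamp intensities to ``[lower, P99.5]`` and linearly rescale the whole
   volume to mean 0 and standard deviation 1.

Clamping (rather than discarding) out-of-range voxels preserves the grid for
downstream cropping.  The upper percentile is computed on the resampled,
unclipped volume.  In adaptive mode a scan whose histogram yields no usable
soft-tissue peak falls back to the percentile baseline with a warning, so
batch runs never abort on one pathological scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .histogram import (
    FitFailureError,
    NoPeakError,
    PeakSearchParams,
    ThresholdResult,
    adaptive_threshold,
)
from .volume import CbctError, LabelVolume, Volume

__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "resample_isotropic",
    "clip_normalize",
    "preprocess_case",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Standardization parameters.

    ``target_spacing`` 0.4 mm; intensities kept from the bone threshold (or
    the ``baseline_lower_percentile`` in baseline mode) up to
    ``upper_percentile`` of the volume, then z-normalized.
    """

    target_spacing: float = 0.4
    upper_percentile: float = 99.5
    mode: str = "adaptive"  # "adaptive" | "percentile-baseline"
    baseline_lower_percentile: float = 0.5
    sigma_factor: float = 3.0
    bin_width: float = 1.0
    peak_params: PeakSearchParams = field(default_factory=PeakSearchParams)

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise CbctError("target_spacing must be positive")
        if not 0 < self.baseline_lower_percentile < self.upper_percentile < 100:
            raise CbctError(
                "need 0 < baseline_lower_percentile < upper_percentile < 100"
            )
        if self.mode not in ("adaptive", "percentile-baseline"):
            raise CbctError(f"unknown mode {self.mode!r}")


@dataclass
class PreprocessResult:
    """Preprocessed volume plus full provenance of the path taken."""

    volume: Volume
    mode_requested: str
    mode_used: str  # "adaptive" | "percentile-baseline"
    clip_lower: float
    clip_upper: float
    threshold: ThresholdResult | None = None
    fallback_reason: str | None = None

    def to_dict(self) -> dict:
        out = {
            "mode_requested": self.mode_requested,
            "mode_used": self.mode_used,
            "clip_lower": self.clip_lower,
            "clip_upper": self.clip_upper,
            "fallback_reason": self.fallback_reason,
        }
        if self.threshold is not None:
            out["threshold"] = self.threshold.to_dict()
        return out


def _to_sitk(volume: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(volume.values))
    img.SetSpacing(tuple(reversed(volume.spacing)))  # sitk wants (x, y, z)
    img.SetOrigin(tuple(reversed(volume.origin)))
    return img


def _from_sitk(img: sitk.Image, labels: bool) -> Volume:
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    cls = LabelVolume if labels else Volume
    return cls(values, spacing, origin)


def resample_isotropic(
    volume: Volume, target_spacing: float = 0.4, interpolation: str | None = None
) -> Volume:
    """Resample to isotropic ``target_spacing`` mm.

    Output dims are ``round(dim * spacing / target)`` (min 1) per axis, so the
    physical extent is preserved to within one voxel.  Images use linear
    interpolation, label volumes nearest-neighbour (never invents labels);
    passing ``interpolation`` overrides the default for the input type.
    """
    if target_spacing <= 0:
        raise CbctError("target_spacing must be positive")
    is_labels = isinstance(volume, LabelVolume)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    if interpolation not in ("linear", "nearest"):
        raise CbctError(f"unknown interpolation {interpolation!r}")
    if is_labels and interpolation != "nearest":
        raise CbctError("label volumes must use nearest interpolation")
    if volume.spacing == (target_spacing,) * 3:
        return volume
    new_shape = tuple(
        max(1, int(round(dim * sp / target_spacing)))
        for dim, sp in zip(volume.shape, volume.spacing)
    )
    img = _to_sitk(volume)
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    # Nearest-neighbour extrapolation: queries just past the last voxel
    # center take the border value instead of an arbitrary zero fill, which
    # would bias border intensities on every resample.
    out = sitk.Resample(
        img,
        tuple(reversed(new_shape)),
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_spacing,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
        True,
    )
    return _from_sitk(out, labels=is_labels)


def clip_normalize(volume: Volume, lower: float, upper_percentile: float = 99.5) -> Volume:
    """Clamp to ``[lower, P_upper]`` then z-normalize (population std).

    Raises on zero variance after clamping (degenerate volume) and on a lower
    bound at or above the upper percentile value.
    """
    values = np.asarray(volume.values, float)
    upper = float(np.percentile(values, upper_percentile))
    if lower >= upper:
        raise CbctError(
            f"lower clip {lower:.1f} is not below the {upper_percentile} "
            f"percentile value {upper:.1f}"
        )
    clipped = np.clip(values, lower, upper)
    std = float(clipped.std())
    if std == 0.0:
        raise CbctError("zero variance after clamping: degenerate volume")
    return volume.with_values((clipped - clipped.mean()) / std)


def preprocess_case(
    volume: Volume, config: PreprocessConfig | None = None
) -> PreprocessResult:
    """Resample, threshold (adaptive or baseline), clip and normalize.

    Returns the standardized volume together with the clip bounds, the
    threshold analysis (adaptive path) and which path actually ran.
    """
    config = config or PreprocessConfig()
    resampled = resample_isotropic(volume, config.target_spacing, "linear")
    values = np.asarray(resampled.values, float)
    upper = float(np.percentile(values, config.upper_percentile))

    threshold: ThresholdResult | None = None
    fallback_reason: str | None = None
    mode_used = config.mode
    if config.mode == "adaptive":
        try:
            threshold = adaptive_threshold(
                resampled,
                config.peak_params,
                config.sigma_factor,
                config.bin_width,
            )
            lower = threshold.x_b
            log.info(
                "adaptive threshold: x_s=%.1f sigma=%.1f x_b=%.1f",
                threshold.x_s,
                threshold.fit.sigma,
                threshold.x_b,
            )
        except (NoPeakError, FitFailureError) as exc:
            fallback_reason = f"{exc.reason_code}: {exc}"
            warnings.warn(
                f"adaptive thresholding failed ({fallback_reason}); "
                "falling back to percentile baseline",
                stacklevel=2,
            )
            log.warning("adaptive threshold failed (%s); using baseline", exc)
            mode_used = "percentile-baseline"
            lower = float(np.percentile(values, config.baseline_lower_percentile))
    else:
        mode_used = "percentile-baseline"
        lower = float(np.percentile(values, config.baseline_lower_percentile))

    normalized = clip_normalize(resampled, lower, config.upper_percentile)
    return PreprocessResult(
        volume=normalized,
        mode_requested=config.mode,
        mode_used=mode_used,
        clip_lower=lower,
        clip_upper=upper,
        threshold=threshold,
        fallback_reason=fallback_reason,
    )
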