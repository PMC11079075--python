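"""Synthetic dental-CBCT phantom with paired ground-truth labels.

The phantom reproduces the histogram structure the adaptive preprocessing
assumes rather than anatomy: one or two narrow spikes (air, and optionally
the constant fill value outside the scanner's field of view) plus a single
broad Gaussian soft-tissue peak, with bone and teeth forming no distinct
peak of their own.  Geometry is parametric: an ellipsoidal soft-tissue head
containing two annular bone arches (maxilla, mandible), ellipsoidal teeth
placed along the arches and labeled with FDI two-digit codes, a toroidal
mandibular canal inside the mandible and an ellipsoidal maxillary sinus in
the upper jaw.

Voxel intensities are the class base value plus Gaussian noise (air and
outside-FOV voxels are exact constants — that is what makes them spikes),
followed by an affine "manufacturer profile" transform emulating the
uncalibrated gray ranges of different CBCT devices.  Labels are the exact
pre-noise geometry.  Teeth are sized so they occupy 1-3 % of the volume,
the class-imbalance regime typical of real dental CBCT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CbctError, FDI_TOOTH_CODES, LabelVolume, Volume

__all__ = [
    "PhantomConfig",
    "PhantomGeometryError",
    "generate_phantom",
    "apply_intensity_profile",
    "perturb_labels",
    "MANUFACTURER_PROFILES",
]


class PhantomGeometryError(CbctError):
    """Requested geometry does not fit the volume dimensions."""


#: Synthetic scale/shift presets emulating inter-device gray-range variability.
#: Names and values are invented stand-ins, not measurements of real scanners.
#: Scales stay within 0.5-2x: much beyond that the soft-tissue peak flattens
#: below the fixed 0.1 % height floor at unit bin width, and a coarser
#: histogram binning would be needed (see the methods note).
MANUFACTURER_PROFILES: dict[str, tuple[float, float]] = {
    "device-A": (1.0, 0.0),
    "device-B": (2.0, 100.0),
    "device-C": (0.7, 400.0),
    "device-D": (1.5, -150.0),
    "device-E": (1.8, 800.0),
    "device-F": (0.5, 1200.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry and intensity model.

    Gray values are arbitrary units (CBCT is uncalibrated).  Soft tissue is
    N(``soft_tissue_mean``, ``soft_tissue_std``); bone sits ``bone_offset``
    above the soft-tissue mean (at least 5 standard deviations, so the modes
    are well separated), teeth ``tooth_offset`` above.  ``noise_std`` is the
    within-class noise of the labeled structures.  ``intensity_scale`` and
    ``intensity_shift`` apply a final affine "manufacturer" transform.
    """

    dims: tuple[int, int, int] = (96, 128, 128)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    air_value: float = 0.0
    outside_fov_value: float | None = -100.0
    soft_tissue_mean: float = 300.0
    soft_tissue_std: float = 40.0
    bone_offset: float = 300.0
    tooth_offset: float = 500.0
    missing_fdi: frozenset = field(default_factory=frozenset)
    target_tooth_fraction: float = 0.02
    noise_std: float = 25.0
    intensity_scale: float = 1.0
    intensity_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 32 for d in self.dims):
            raise CbctError("phantom dims must each be >= 32")
        if not self.tooth_offset > self.bone_offset > 0:
            raise CbctError("need tooth_offset > bone_offset > 0")
        if self.bone_offset < 5 * self.soft_tissue_std:
            raise CbctError("bone_offset must be >= 5 soft-tissue stds")
        if not 0 < self.target_tooth_fraction < 0.1:
            raise CbctError("target_tooth_fraction must be in (0, 0.1)")
        if self.intensity_scale <= 0:
            raise CbctError("intensity_scale must be positive")
        object.__setattr__(self, "missing_fdi", frozenset(int(c) for c in self.missing_fdi))


def _ellipsoid(zz, yy, xx, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _build_labels(config: PhantomConfig):
    """Paint the label volume and return it with the geometry bookkeeping."""
    dz, dy, dx = config.dims
    zz, yy, xx = np.ogrid[0:dz, 0:dy, 0:dx]
    cz, cy, cx = (dz - 1) / 2.0, (dy - 1) / 2.0, (dx - 1) / 2.0
    dmin = min(dy, dx)

    head = _ellipsoid(zz, yy, xx, (cz, cy, cx), (0.46 * dz, 0.44 * dy, 0.44 * dx))
    r_inplane = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) + 0.0 * zz

    ring_radius = 0.30 * dmin
    ring_halfwidth = 0.045 * dmin
    in_ring = np.abs(r_inplane - ring_radius) <= ring_halfwidth

    labels = np.zeros(config.dims, dtype=np.int32)
    maxilla = in_ring & (zz >= 0.60 * dz) & (zz <= 0.78 * dz)
    mandible = in_ring & (zz >= 0.22 * dz) & (zz <= 0.40 * dz)
    labels[maxilla & head] = 1
    labels[mandible & head] = 2

    sinus = _ellipsoid(
        zz, yy, xx,
        (0.74 * dz, cy - 0.10 * dy, cx),
        (0.07 * dz + 1, 0.07 * dy + 1, 0.07 * dx + 1),
    )
    labels[sinus] = 3

    canal_z = 0.28 * dz
    canal_minor = min(4.5, ring_halfwidth - 0.5)
    canal = np.sqrt((r_inplane - ring_radius) ** 2 + (zz - canal_z) ** 2) <= canal_minor
    labels[canal & (labels == 2)] = 4

    # Teeth: ellipsoids on the arch ring, 16 per arch.  In-plane radii are
    # solved from the target voxel fraction; the axial semi-axis is fixed.
    codes = [c for c in FDI_TOOTH_CODES if c not in config.missing_fdi]
    n_total = len(FDI_TOOTH_CODES)
    tooth_az = max(4.0, round(dz / 16))
    per_tooth = config.target_tooth_fraction * dz * dy * dx / n_total
    tooth_axy = float(np.sqrt(3.0 * per_tooth / (4.0 * np.pi * tooth_az)))
    chord = 2.0 * ring_radius * np.sin(np.pi / 16.6)  # adjacent tooth spacing
    if 2 * tooth_axy > chord - 1:
        raise PhantomGeometryError(
            f"teeth of radius {tooth_axy:.1f} voxels cannot reach the target "
            f"fraction {config.target_tooth_fraction} without overlapping on "
            f"a ring of radius {ring_radius:.1f}; increase dims"
        )
    upper_z, lower_z = 0.58 * dz, 0.42 * dz
    # FDI quadrants: 1 upper right, 2 upper left, 3 lower left, 4 lower right;
    # positions 1-8 run from the front (angle 0 at +y) outward.
    for code in codes:
        quadrant, position = divmod(code, 10)
        angle = (np.pi / 8.3) * (position - 0.5)
        if quadrant in (1, 4):
            angle = -angle
        z0 = upper_z if quadrant in (1, 2) else lower_z
        y0 = cy + ring_radius * np.cos(angle)
        x0 = cx + ring_radius * np.sin(angle)
        tooth = _ellipsoid(zz, yy, xx, (z0, y0, x0), (tooth_az, tooth_axy, tooth_axy))
        labels[tooth] = code

    fov = None
    if config.outside_fov_value is not None:
        fov = (r_inplane + 0.0 * zz) > 0.49 * dmin
    return labels, head, fov


def generate_phantom(config: PhantomConfig | None = None) -> tuple[Volume, LabelVolume]:
    """Generate a phantom volume and its exact label map.

    Deterministic for a fixed ``config.seed``.  Raises
    :class:`PhantomGeometryError` if teeth cannot reach the target fraction
    inside the given dims.
    """
    config = config or PhantomConfig()
    labels, head, fov = _build_labels(config)

    tooth_mask = labels >= 11
    frac = tooth_mask.mean()
    if not 0.5 * config.target_tooth_fraction <= frac <= 1.5 * config.target_tooth_fraction:
        raise PhantomGeometryError(
            f"tooth fraction {frac:.4f} far from target "
            f"{config.target_tooth_fraction}; increase dims"
        )

    base = np.full(config.dims, config.air_value, dtype=float)
    noise_scale = np.zeros(config.dims, dtype=float)
    soft = head & (labels == 0)
    base[soft] = config.soft_tissue_mean
    noise_scale[soft] = config.soft_tissue_std
    bone = (labels == 1) | (labels == 2)
    base[bone] = config.soft_tissue_mean + config.bone_offset
    base[labels == 3] = config.air_value  # sinus is an air cavity
    base[labels == 4] = config.soft_tissue_mean  # nerve canal is soft tissue
    noise_scale[(labels >= 1) & (labels <= 4)] = config.noise_std
    base[tooth_mask] = config.soft_tissue_mean + config.tooth_offset
    noise_scale[tooth_mask] = config.noise_std
    if fov is not None:
        base[fov] = config.outside_fov_value
        noise_scale[fov] = 0.0
        labels = np.where(fov, 0, labels)

    rng = np.random.default_rng(config.seed)
    values = base + noise_scale * rng.standard_normal(config.dims)
    values = config.intensity_scale * values + config.intensity_shift

    volume = Volume(values, config.spacing)
    label_volume = LabelVolume(labels, config.spacing)
    return volume, label_volume


def apply_intensity_profile(volume: Volume, scale: float, shift: float) -> Volume:
    """Affine gray transform ``v -> scale * v + shift`` (manufacturer profile)."""
    if scale <= 0:
        raise CbctError("intensity scale must be positive")
    return volume.with_values(scale * np.asarray(volume.values, float) + shift)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r**2


def perturb_labels(
    labels: LabelVolume,
    kind: str,
    magnitude: int,
    seed: int = 0,
    offset: tuple[int, int, int] | None = None,
) -> LabelVolume:
    """Degrade a label volume to emulate an imperfect prediction.

    ``kind`` is ``"erode"`` or ``"dilate"`` (per-class morphology with a ball
    of radius ``magnitude`` voxels) or ``"shift"`` (rigid integer translation
    by ``offset``, defaulting to ``magnitude`` voxels along a seed-chosen
    axis).  Magnitude 0 is the identity.  Dilation fills background only, so
    existing classes keep their voxels.
    """
    if magnitude < 0:
        raise CbctError("magnitude must be >= 0")
    if kind not in ("erode", "dilate", "shift"):
        raise CbctError(f"unknown perturbation kind: {kind!r}")
    arr = np.asarray(labels.values)
    if magnitude == 0:
        return LabelVolume(arr.copy(), labels.spacing, labels.origin)

    if kind == "shift":
        if offset is None:
            rng = np.random.default_rng(seed)
            axis = int(rng.integers(0, 3))
            sign = int(rng.integers(0, 2)) * 2 - 1
            offset = tuple(sign * magnitude if a == axis else 0 for a in range(3))
        out = np.zeros_like(arr)
        src = tuple(
            slice(max(0, -o), min(d, d - o)) for o, d in zip(offset, arr.shape)
        )
        dst = tuple(
            slice(max(0, o), min(d, d + o)) for o, d in zip(offset, arr.shape)
        )
        out[dst] = arr[src]
        return LabelVolume(out, labels.spacing, labels.origin)

    structure = _ball(magnitude)
    classes = [int(c) for c in np.unique(arr) if c != 0]
    if kind == "erode":
        out = np.zeros_like(arr)
        for c in classes:
            eroded = ndimage.binary_erosion(arr == c, structure=structure, border_value=0)
            out[eroded] = c
    else:
        out = arr.copy()
        for c in classes:
            grown = ndimage.binary_dilation(arr == c, structure=structure)
            out[grown & (out == 0)] = c
    return LabelVolume(out, labels.spacing, labels.origin)
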