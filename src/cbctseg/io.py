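"""Volume readers/writers: NIfTI and NRRD files, DICOM series directories.

NIfTI is the canonical interchange format; DICOM is read-only input.  On
read, images are converted to the package's internal ``(z, y, x)`` array
convention (SimpleITK's array ordering) with spacing and origin carried in
mm.  Label reads validate that the data are integer-valued.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volume import CbctError, LabelVolume, Volume

__all__ = ["read_volume", "write_volume"]

_FILE_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr", ".mha", ".mhd")


class UnknownFormatError(CbctError):
    """Path is neither a supported image file nor a DICOM series directory."""


class InconsistentSeriesError(CbctError):
    """DICOM series has non-uniform slice spacing."""


def _from_sitk(img: sitk.Image, labels: bool) -> Volume | LabelVolume:
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if labels:
        if not np.issubdtype(values.dtype, np.integer) and not np.allclose(
            values, np.round(values)
        ):
            raise CbctError(f"label data are not integer-valued")
        return LabelVolume(np.round(values).astype(np.int32), spacing, origin)
    return Volume(values.astype(float), spacing, origin)


def _read_dicom_series(path: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise UnknownFormatError(f"no DICOM series found in {path}")
    # Validate uniform slice spacing from the per-slice positions.
    positions = []
    file_reader = sitk.ImageFileReader()
    for name in names:
        file_reader.SetFileName(name)
        file_reader.ReadImageInformation()
        positions.append(float(file_reader.GetOrigin()[2]))
    steps = np.diff(sorted(positions))
    if len(steps) and not np.allclose(steps, steps[0], atol=1e-3):
        raise InconsistentSeriesError(
            f"DICOM series in {path} has mixed slice spacing: "
            f"steps range {steps.min():.4f}-{steps.max():.4f} mm"
        )
    reader.SetFileNames(names)
    return reader.Execute()


def read_volume(path: str | os.PathLike, labels: bool = False) -> Volume | LabelVolume:
    """Read a volume from NIfTI/NRRD/MetaImage or a DICOM series directory.

    ``labels=True`` validates integer-valued data and returns a
    :class:`LabelVolume`.
    """
    p = Path(path)
    if p.is_dir():
        img = _read_dicom_series(p)
    elif p.is_file():
        name = p.name.lower()
        if not any(name.endswith(s) for s in _FILE_SUFFIXES):
            raise UnknownFormatError(f"unsupported volume format: {p.name}")
        img = sitk.ReadImage(str(p))
    else:
        raise CbctError(f"input path does not exist: {p}")
    return _from_sitk(img, labels)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume (NIfTI/NRRD by extension), preserving geometry.

    Label volumes are written as integers, images as float32.
    """
    p = Path(path)
    values = np.asarray(volume.values)
    if isinstance(volume, LabelVolume):
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float32)
    img = sitk.GetImageFromArray(values)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    p.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(p))
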