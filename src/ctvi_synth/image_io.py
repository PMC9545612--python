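"""Volumetric image I/O with explicit grid geometry.

All in-memory volumes use (z, y, x) axis order: z is the axial slice index
(superior-inferior), y anterior-posterior, x left-right.  The 2D network
consumes axial slices, so z leads.  Supported on-disk formats are NIfTI-1
(.nii / .nii.gz, via nibabel) and MetaImage (.mha / .mhd, via SimpleITK).
Only axis-aligned orientations are accepted; oblique acquisitions are
rejected rather than silently resampled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, ParameterError

#: Valid physical-units tags for a volume.
UNITS = ("HU", "kBq_per_mL", "normalized", "boolean")


@dataclass
class ImageVolume:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    data:
        3D array in (z, y, x) order.
    spacing:
        Voxel spacing (sz, sy, sx) in millimetres, strictly positive.
    origin:
        Physical position (oz, oy, ox) of voxel (0, 0, 0) in millimetres.
    units:
        One of ``HU``, ``kBq_per_mL``, ``normalized``, ``boolean``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.units not in UNITS:
            raise ParameterError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if not np.isfinite(self.data).all():
            n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
            raise FormatError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.units == "boolean":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ParameterError("boolean volume has values outside {0, 1}")
        elif self.units == "normalized":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ParameterError(
                    f"normalized volume has values outside [0, 1]: [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def with_data(self, data: np.ndarray, units: str | None = None) -> "ImageVolume":
        """Same grid, new voxel values (and optionally a new units tag)."""
        return replace(self, data=data, units=units if units is not None else self.units)


def _background_value(units: str) -> float:
    """Fill value representing 'nothing there' for a given units tag."""
    return -1000.0 if units == "HU" else 0.0


def _check_axis_aligned(mat: np.ndarray, what: str) -> np.ndarray:
    """Require a 3x3 orientation matrix to be diagonal up to sign.

    Returns the sign of each diagonal entry.  Off-diagonal terms or zero
    scales are rejected: the pipeline never handles oblique volumes.
    """
    mat = np.asarray(mat, dtype=float)
    off = mat - np.diag(np.diag(mat))
    if np.abs(off).max() > 1e-4 * max(1.0, np.abs(mat).max()):
        raise FormatError(f"{what}: orientation is not axis-aligned")
    d = np.diag(mat)
    if np.any(d == 0):
        raise FormatError(f"{what}: zero scale in orientation/spacing")
    return np.sign(d)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _is_metaimage(path: Path) -> bool:
    return path.suffix.lower() in (".mha", ".mhd")


def read_volume(path: str | os.PathLike, expected_units: str = "HU") -> ImageVolume:
    """Read a NIfTI or MetaImage volume into canonical (z, y, x) order.

    Geometry (spacing, origin) is taken from the header.  Axes with negative
    direction are flipped to positive so that in-memory data always increases
    along +z, +y, +x; the origin is adjusted accordingly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - backend specific
            raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
        affine = np.asarray(img.affine, dtype=float)
        signs = _check_axis_aligned(affine[:3, :3], str(path))
        data_xyz = np.asanyarray(img.dataobj)
        if data_xyz.ndim != 3:
            raise FormatError(f"{path}: expected a 3D volume, got {data_xyz.ndim}D")
        spacing_xyz = np.abs(np.diag(affine[:3, :3]))
        origin_xyz = affine[:3, 3].copy()
        for ax in range(3):
            if signs[ax] < 0:
                data_xyz = np.flip(data_xyz, axis=ax)
                origin_xyz[ax] -= spacing_xyz[ax] * (data_xyz.shape[ax] - 1)
        data = np.ascontiguousarray(np.transpose(data_xyz, (2, 1, 0)))
        spacing = tuple(spacing_xyz[::-1])
        origin = tuple(origin_xyz[::-1])
    elif _is_metaimage(path):
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise FormatError(f"unreadable MetaImage file {path}: {exc}") from exc
        direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
        signs = _check_axis_aligned(direction, str(path))
        if np.any(signs < 0):
            raise FormatError(f"{path}: negative direction cosines are not supported")
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
        spacing = tuple(np.asarray(img.GetSpacing(), dtype=float)[::-1])
        origin = tuple(np.asarray(img.GetOrigin(), dtype=float)[::-1])
    else:
        raise FormatError(
            f"unsupported format for {path}: expected .nii/.nii.gz/.mha/.mhd"
        )
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: header spacing missing or non-positive: {spacing}")
    if expected_units == "boolean":
        data = (np.asarray(data) != 0).astype(np.uint8)
    elif np.issubdtype(np.asarray(data).dtype, np.floating):
        data = np.asarray(data, dtype=np.float32)
    return ImageVolume(data=data, spacing=spacing, origin=origin, units=expected_units)


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI or MetaImage, inferring format from suffix.

    Float data is stored as float32; boolean masks as uint8 {0, 1}.
    ``read_volume(write_volume(v))`` is the identity on data, spacing and
    origin (float data at float32 precision).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FormatError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(vol.data)
    if vol.units == "boolean":
        data = (data != 0).astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    if _is_nifti(path):
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = (ox, oy, oz)
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))
    elif _is_metaimage(path):
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((sx, sy, sz))
        img.SetOrigin((ox, oy, oz))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(
            f"unsupported format for {path}: expected .nii/.nii.gz/.mha/.mhd"
        )


@dataclass
class CTVolumePair:
    """Exhale and inhale breath-hold CT volumes sharing one grid."""

    exhale: ImageVolume
    inhale: ImageVolume

    def __post_init__(self) -> None:
        for v in (self.exhale, self.inhale):
            if v.units != "HU":
                raise ParameterError("CTVolumePair volumes must be in HU")
        if self.exhale.shape != self.inhale.shape:
            raise ParameterError(
                f"exhale/inhale shapes differ: {self.exhale.shape} vs {self.inhale.shape}"
            )
        if not np.allclose(self.exhale.spacing, self.inhale.spacing) or not np.allclose(
            self.exhale.origin, self.inhale.origin
        ):
            raise ParameterError("exhale/inhale grids (spacing/origin) differ")
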