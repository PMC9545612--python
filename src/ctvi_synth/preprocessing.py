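"""CT / ventilation preprocessing.

Turns a raw exhale/inhale CT pair plus a co-registered ventilation (activity)
volume into the fixed-size, normalized 3-channel stack the network trains on:

1. resample everything to an isotropic grid (B-spline for images),
2. optional rigid shift supplied by configuration (the clinical alignment
   step, which was manual, is replaced by an explicit shift vector),
3. lung segmentation on each CT phase by HU thresholding + morphology,
4. mask the CTs with the union (exhale OR inhale) lung mask,
5. crop/pad to the target shape centred on the union-mask centroid,
6. per-case min-max normalization of the CTs over the whole cropped volume,
7. activity standardization: clip at mu + k*sigma of lung activity, then
   global min-max normalization.

All steps are deterministic: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateCaseError, ParameterError
from .image_io import CTVolumePair, ImageVolume, _background_value

log = logging.getLogger(__name__)

#: HU threshold below which voxels are lung/air candidates.
DEFAULT_HU_THRESHOLD = -500.0
#: Default clip multiplier in the mu + k*sigma activity standardization.
DEFAULT_SIGMA_CLIP_K = 4.0
#: Network-facing crop shape (z, y, x) at full scale.
DEFAULT_CROP_SHAPE = (250, 304, 304)


@dataclass
class LungMask:
    """Boolean lung segmentation tied to the phase it was derived from."""

    data: np.ndarray
    source: str = "exhale"  # one of {exhale, inhale, union}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ParameterError("lung mask must be 3D")
        if self.source not in ("exhale", "inhale", "union"):
            raise ParameterError(f"unknown mask source {self.source!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class PreprocessedCase:
    """Network-ready case: 3-channel input stack, 1-channel label, masks.

    ``channels`` has shape (3, z, y, x) with channel order (exhale, inhale,
    average); ``label`` has shape (z, y, x).  All values lie in [0, 1].
    """

    channels: np.ndarray
    label: np.ndarray
    exhale_mask: LungMask
    union_mask: LungMask
    case_id: str

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.label = np.asarray(self.label, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ParameterError("channels must have shape (3, z, y, x)")
        if self.label.shape != self.channels.shape[1:]:
            raise ParameterError("label grid differs from channel grid")
        for m in (self.exhale_mask, self.union_mask):
            if m.shape != self.label.shape:
                raise ParameterError("mask grid differs from channel grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.label.shape)


def resample_isotropic(
    vol: ImageVolume,
    target_spacing_mm: float = 1.0,
    interpolation_order: int = 3,
) -> ImageVolume:
    """Resample to an isotropic grid with spline interpolation.

    The output size per axis is round(size * spacing / target).  Spline
    overshoot is clamped to the input intensity range so resampling never
    invents values outside it.
    """
    if target_spacing_mm <= 0:
        raise ParameterError(f"target spacing must be positive, got {target_spacing_mm}")
    in_shape = np.array(vol.shape, dtype=float)
    in_spacing = np.array(vol.spacing, dtype=float)
    out_shape = np.maximum(1, np.round(in_shape * in_spacing / target_spacing_mm)).astype(int)
    if np.all(out_shape == vol.shape) and np.allclose(in_spacing, target_spacing_mm):
        return vol.with_data(vol.data.copy())
    zoom = out_shape / in_shape
    # edge replication at the boundary: a constant far-field background would
    # leak spline-prefilter ringing several voxels into the volume
    data = ndimage.zoom(
        np.asarray(vol.data, dtype=np.float32),
        zoom,
        order=interpolation_order,
        mode="nearest",
        grid_mode=True,
    )
    data = np.clip(data, vol.data.min(), vol.data.max())
    out = ImageVolume(
        data=data.astype(np.float32),
        spacing=(target_spacing_mm,) * 3,
        origin=vol.origin,
        units=vol.units,
    )
    return out


def apply_rigid_shift(
    vol: ImageVolume, shift_mm: tuple[float, float, float]
) -> ImageVolume:
    """Translate a volume by (dz, dy, dx) millimetres with linear interpolation.

    Regions shifted in from outside the volume are filled with the background
    value for the volume's units (HU -> -1000, activity/normalized -> 0).
    """
    shift_vox = np.asarray(shift_mm, dtype=float) / np.asarray(vol.spacing)
    if np.allclose(shift_vox, 0):
        return vol.with_data(vol.data.copy())
    data = ndimage.shift(
        np.asarray(vol.data, dtype=np.float32),
        shift_vox,
        order=1,
        mode="constant",
        cval=_background_value(vol.units),
    )
    return vol.with_data(data.astype(np.float32))


def compute_lung_mask(
    ct: ImageVolume,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    closing_radius_vox: int = 2,
    min_component_vox: int = 100,
    case_id: str = "<unnamed>",
    source: str = "exhale",
) -> LungMask:
    """Segment the lungs from a CT volume.

    Pipeline: threshold ct < hu_threshold; discard the air component touching
    the volume border (outside air) by connected-component flood fill; keep
    the at-most-2 largest remaining components with at least
    ``min_component_vox`` voxels; morphological closing to fill vessels and
    airway walls.
    """
    if ct.units != "HU":
        raise ParameterError("lung masking expects a CT in HU")
    below = np.asarray(ct.data) < hu_threshold
    labels, n_labels = ndimage.label(below)
    if n_labels == 0:
        raise DegenerateCaseError(
            f"case {case_id}: no voxels below {hu_threshold} HU — empty lung mask"
        )
    # labels of components touching the border = outside air
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    counts[border_labels] = 0
    keep = np.flatnonzero(counts >= min_component_vox)
    if keep.size == 0:
        raise DegenerateCaseError(
            f"case {case_id}: no interior low-HU component with >= "
            f"{min_component_vox} voxels — empty lung mask"
        )
    keep = keep[np.argsort(counts[keep])[::-1][:2]]
    mask = np.isin(labels, keep)
    if closing_radius_vox > 0:
        r = int(closing_radius_vox)
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = (zz**2 + yy**2 + xx**2) <= r**2
        mask = ndimage.binary_closing(mask, structure=ball)
    log.info(
        "case %s: lung mask (%s) %d voxels from threshold %g HU",
        case_id, source, int(mask.sum()), hu_threshold,
    )
    return LungMask(data=mask, source=source)


def union_mask(a: LungMask, b: LungMask) -> LungMask:
    """Voxelwise OR of two lung masks."""
    if a.shape != b.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return LungMask(data=a.data | b.data, source="union")


def mask_ct(ct: ImageVolume, mask: LungMask, fill_hu: float = -1000.0) -> ImageVolume:
    """Set voxels outside the mask to ``fill_hu``; voxels inside untouched."""
    if tuple(ct.shape) != tuple(mask.shape):
        raise ParameterError(f"CT shape {ct.shape} differs from mask shape {mask.shape}")
    data = np.where(mask.data, ct.data, fill_hu).astype(np.float32)
    return ct.with_data(data)


def _crop_or_pad_array(
    data: np.ndarray,
    target_shape: tuple[int, int, int],
    fill: float,
    center: np.ndarray,
) -> np.ndarray:
    out = np.full(target_shape, fill, dtype=data.dtype)
    start = np.round(center - np.asarray(target_shape) / 2.0).astype(int)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.asarray(target_shape), data.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        return out
    out[
        dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]
    ] = data[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]]
    return out


def crop_or_pad(
    vol: ImageVolume,
    target_shape: tuple[int, int, int] = DEFAULT_CROP_SHAPE,
    fill: float | None = None,
    mask: LungMask | None = None,
) -> ImageVolume:
    """Crop and/or pad to ``target_shape``, centred on the mask centroid.

    Without a mask the volume centre is used.  Padding uses the background
    value for the units unless ``fill`` is given.
    """
    if fill is None:
        fill = _background_value(vol.units)
    if mask is not None and mask.n_voxels > 0:
        center = np.array(ndimage.center_of_mass(mask.data))
        # +0.5: centroid in continuous voxel coordinates
        center = center + 0.5
    else:
        center = np.asarray(vol.shape) / 2.0
    data = _crop_or_pad_array(
        np.asarray(vol.data), tuple(target_shape), float(fill), center
    )
    return ImageVolume(data, spacing=vol.spacing, origin=vol.origin, units=vol.units)


def crop_or_pad_mask(
    mask: LungMask,
    target_shape: tuple[int, int, int],
    center_mask: LungMask | None = None,
) -> LungMask:
    """Crop/pad a boolean mask on the same window as :func:`crop_or_pad`."""
    ref = center_mask if center_mask is not None else mask
    if ref.n_voxels > 0:
        center = np.array(ndimage.center_of_mass(ref.data)) + 0.5
    else:
        center = np.asarray(mask.shape) / 2.0
    data = _crop_or_pad_array(mask.data, tuple(target_shape), 0, center)
    return LungMask(data=data.astype(bool), source=mask.source)


def minmax_normalize(vol: ImageVolume, region: LungMask | None = None) -> ImageVolume:
    """Min-max normalize to [0, 1].

    The minimum and maximum are computed over ``region`` when given (else the
    whole volume) and the affine rescale is applied to every voxel, then
    clipped to [0, 1].  A constant volume maps to all zeros.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if region is not None:
        if region.shape != vol.shape:
            raise ParameterError("normalization region shape differs from volume")
        vals = data[region.data]
        if vals.size == 0:
            raise ParameterError("normalization region is empty")
    else:
        vals = data
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        out = np.zeros_like(data, dtype=np.float32)
    else:
        out = np.clip((data - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    return vol.with_data(out, units="normalized")


def standardize_activity(
    pet: ImageVolume,
    lung: LungMask,
    sigma_clip_k: float = DEFAULT_SIGMA_CLIP_K,
    case_id: str = "<unnamed>",
) -> ImageVolume:
    """Clip activity hot spots at mu + k*sigma of lung activity, then normalize.

    mu and sigma (population form) are computed over lung voxels only; the
    clip ``v <- min(v, mu + k*sigma)`` is applied to every voxel of the
    volume; finally the whole volume is min-max normalized to [0, 1].  This
    keeps rare radio-aerosol clumping spikes from compressing the remaining
    signal into a sliver of the normalized range.
    """
    if tuple(pet.shape) != tuple(lung.shape):
        raise ParameterError("activity volume and lung mask shapes differ")
    if lung.n_voxels == 0:
        raise DegenerateCaseError(f"case {case_id}: empty lung mask in standardization")
    vals = np.asarray(pet.data, dtype=np.float64)[lung.data]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population (ddof=0)
    threshold = mu + sigma_clip_k * sigma
    clipped = np.minimum(np.asarray(pet.data, dtype=np.float64), threshold)
    frac = float((np.asarray(pet.data) > threshold).mean())
    log.info(
        "case %s: activity standardization mu=%.4g sigma=%.4g clip=%.4g "
        "(%.4f%% voxels clipped)", case_id, mu, sigma, threshold, 100 * frac,
    )
    return minmax_normalize(pet.with_data(clipped.astype(np.float32)))


def assemble_case(
    pair: CTVolumePair,
    vent: ImageVolume,
    exhale_mask: LungMask,
    union: LungMask,
    case_id: str,
) -> PreprocessedCase:
    """Build the 3-channel input stack and label from co-gridded volumes.

    Channel 1 = normalized union-masked exhale CT, channel 2 = normalized
    union-masked inhale CT, channel 3 = voxelwise mean of channels 1 and 2.
    The label is the standardized + normalized ventilation, not additionally
    lung-masked.
    """
    shapes = {pair.exhale.shape, pair.inhale.shape, vent.shape,
              exhale_mask.shape, union.shape}
    if len(shapes) != 1:
        raise ParameterError(f"case {case_id}: volumes are not on a common grid: {shapes}")
    ch1 = minmax_normalize(mask_ct(pair.exhale, union)).data
    ch2 = minmax_normalize(mask_ct(pair.inhale, union)).data
    ch3 = (ch1 + ch2) / 2.0
    if vent.units == "kBq_per_mL":
        label = standardize_activity(vent, union, case_id=case_id).data
    elif vent.units == "normalized":
        label = np.asarray(vent.data, dtype=np.float32)
    else:
        raise ParameterError(f"case {case_id}: label units {vent.units!r} unsupported")
    return PreprocessedCase(
        channels=np.stack([ch1, ch2, ch3]).astype(np.float32),
        label=label.astype(np.float32),
        exhale_mask=exhale_mask,
        union_mask=union,
        case_id=case_id,
    )


def save_preprocessed(case: PreprocessedCase, path) -> None:
    """Persist a PreprocessedCase as a compressed npz archive."""
    np.savez_compressed(
        path,
        channels=case.channels,
        label=case.label,
        exhale_mask=case.exhale_mask.data.astype(np.uint8),
        union_mask=case.union_mask.data.astype(np.uint8),
        case_id=np.array(case.case_id),
    )


def load_preprocessed(path) -> PreprocessedCase:
    with np.load(path) as data:
        return PreprocessedCase(
            channels=data["channels"],
            label=data["label"],
            exhale_mask=LungMask(data["exhale_mask"].astype(bool), source="exhale"),
            union_mask=LungMask(data["union_mask"].astype(bool), source="union"),
            case_id=str(data["case_id"]),
        )


def preprocess_case(
    pair: CTVolumePair,
    vent: ImageVolume,
    case_id: str,
    target_spacing_mm: float = 1.0,
    crop_shape: tuple[int, int, int] = DEFAULT_CROP_SHAPE,
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    closing_radius_vox: int = 2,
    min_component_vox: int = 100,
    sigma_clip_k: float = DEFAULT_SIGMA_CLIP_K,
) -> PreprocessedCase:
    """Full preprocessing chain from raw volumes to a network-ready case."""
    exhale = resample_isotropic(pair.exhale, target_spacing_mm)
    inhale = resample_isotropic(pair.inhale, target_spacing_mm)
    vent_r = resample_isotropic(vent, target_spacing_mm)
    vent_r = apply_rigid_shift(vent_r, shift_mm)

    m_ex = compute_lung_mask(exhale, hu_threshold, closing_radius_vox,
                             min_component_vox, case_id, source="exhale")
    m_in = compute_lung_mask(inhale, hu_threshold, closing_radius_vox,
                             min_component_vox, case_id, source="inhale")
    m_union = union_mask(m_ex, m_in)

    crop = tuple(crop_shape)
    exhale_c = crop_or_pad(exhale, crop, mask=m_union)
    inhale_c = crop_or_pad(inhale, crop, mask=m_union)
    vent_c = crop_or_pad(vent_r, crop, mask=m_union)
    m_ex_c = crop_or_pad_mask(m_ex, crop, center_mask=m_union)
    m_union_c = crop_or_pad_mask(m_union, crop, center_mask=m_union)

    pair_c = CTVolumePair(exhale=exhale_c, inhale=inhale_c)
    if vent_c.units == "kBq_per_mL":
        label_vol = standardize_activity(vent_c, m_union_c,
                                         sigma_clip_k, case_id=case_id)
    else:
        label_vol = vent_c
    return assemble_case(pair_c, label_vol, m_ex_c, m_union_c, case_id)
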