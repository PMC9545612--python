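"""Synthetic thorax phantom: paired breath-hold CT volumes plus a PET-like
ventilation ground truth with known structure.

The phantom encodes the physical link that makes ventilation learnable from
a CT pair: regional air-content change between exhale and inhale lowers the
inhale HU in proportion to local ventilation.  The generated ventilation
field is smooth, concentrated centrally and anteriorly (the qualitative
distribution seen in ventilation imaging of supine patients), zero outside
the lungs, and normalized to [0, 1].  The PET-like volume is the field seen
through an imperfect detector: Gaussian point-spread blur, multiplicative
noise, and rare single-voxel radio-aerosol "clumping" hot spots that are
orders of magnitude brighter than the surrounding signal — the artefact the
mu + 4*sigma standardization rule exists to handle.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import CTVolumePair, ImageVolume, write_volume
from .preprocessing import LungMask


@dataclass
class PhantomSpec:
    """Geometry, physics and noise parameters of one synthetic thorax.

    Lengths are millimetres, intensities Hounsfield units.  Coordinates are
    offsets from the grid centre in (z, y, x) order; y increases from
    anterior to posterior.
    """

    grid_shape: tuple[int, int, int] = (96, 128, 128)
    spacing_mm: float = 2.0
    body_axes_mm: tuple[float, float, float] = (170.0, 82.0, 115.0)
    lung_axes_mm: tuple[tuple[float, float, float], ...] = (
        (52.0, 42.0, 30.0),
        (52.0, 42.0, 30.0),
    )
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (0.0, -6.0, -46.0),
        (0.0, -6.0, 46.0),
    )
    base_lung_hu: float = -800.0
    body_hu: float = 0.0
    air_hu: float = -1000.0
    lung_texture_hu: float = 30.0
    ct_noise_hu: float = 10.0
    vent_blob_count: int = 6
    vent_anterior_bias: float = 0.7
    beta_hu_per_vent: float = 150.0
    tumor: tuple[tuple[float, float, float], float, float] | None = None
    pet_scale_kbq: float = 10.0
    pet_psf_sigma_mm: float = 6.0
    pet_noise_scale: float = 0.15
    n_hotspots: int = 3
    hotspot_multiplier: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_hu_per_vent <= 0:
            raise ParameterError("beta_hu_per_vent must be positive")
        if self.pet_psf_sigma_mm < 0:
            raise ParameterError("pet_psf_sigma_mm must be non-negative")
        if not 0.0 <= self.vent_anterior_bias <= 1.0:
            raise ParameterError("vent_anterior_bias must lie in [0, 1]")
        if len(self.lung_axes_mm) != len(self.lung_centers_mm):
            raise ParameterError("one centre per lung required")


@dataclass
class PhantomCase:
    """One synthetic patient: CT pair, true ventilation, PET-like label."""

    pair: CTVolumePair
    true_vent: ImageVolume
    pet_like: ImageVolume
    true_lung: LungMask
    case_id: str
    seed: int
    spec: PhantomSpec | None = None


def _grid_coords_mm(spec: PhantomSpec):
    """Physical (z, y, x) coordinates of voxel centres, origin at grid centre."""
    axes = []
    for n in spec.grid_shape:
        c = (np.arange(n) - (n - 1) / 2.0) * spec.spacing_mm
        axes.append(c)
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center_mm, axes_mm) -> np.ndarray:
    zz, yy, xx = coords
    cz, cy, cx = center_mm
    az, ay, ax = axes_mm
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _body_and_lung_masks(spec: PhantomSpec):
    coords = _grid_coords_mm(spec)
    body = _ellipsoid(coords, (0.0, 0.0, 0.0), spec.body_axes_mm)
    lung = np.zeros(spec.grid_shape, dtype=bool)
    for center, axes in zip(spec.lung_centers_mm, spec.lung_axes_mm):
        lung |= _ellipsoid(coords, center, axes)
    tumor = np.zeros(spec.grid_shape, dtype=bool)
    if spec.tumor is not None:
        t_center, t_radius, _ = spec.tumor
        tumor = _ellipsoid(coords, t_center, (t_radius,) * 3)
    if not (lung & ~body).sum() == 0:
        raise ParameterError("phantom lungs are not contained in the body")
    if spec.tumor is not None and (tumor & ~lung).sum() > 0:
        raise ParameterError("phantom tumor is not contained in a lung")
    lung = lung & ~tumor  # tumor tissue is not aerated
    return body, lung, tumor


def generate_ventilation_field(spec: PhantomSpec, rng: np.random.Generator) -> ImageVolume:
    """Smooth normalized ventilation: random Gaussian blobs inside the lung,
    weighted toward the anterior-central lung, zero outside the lung."""
    _, lung, _ = _body_and_lung_masks(spec)
    nz, ny, nx = spec.grid_shape
    field = np.zeros(spec.grid_shape, dtype=np.float64)
    lung_idx = np.argwhere(lung)
    coords = _grid_coords_mm(spec)
    for _ in range(spec.vent_blob_count):
        cz, cy, cx = lung_idx[rng.integers(len(lung_idx))]
        sigma = rng.uniform(15.0, 40.0)  # mm
        center = (coords[0][cz, cy, cx], coords[1][cz, cy, cx], coords[2][cz, cy, cx])
        d2 = ((coords[0] - center[0]) ** 2 + (coords[1] - center[1]) ** 2
              + (coords[2] - center[2]) ** 2)
        field += rng.uniform(0.5, 1.0) * np.exp(-d2 / (2 * sigma**2))
    # anterior (low y) and central (mid z) weighting
    b = spec.vent_anterior_bias
    a_ramp = 1.0 - np.arange(ny) / max(ny - 1, 1)
    z_mid = (nz - 1) / 2.0
    c_bump = np.exp(-((np.arange(nz) - z_mid) ** 2) / (2 * (0.35 * nz) ** 2))
    weight = (1 - b) + b * (a_ramp[None, :, None] * c_bump[:, None, None])
    field = field * weight
    field[~lung] = 0.0
    if lung.any() and field[lung].max() > field[lung].min():
        # robust stretch with saturation: the best-ventilated quarter of the
        # lung saturates at 1, the bottom tail at 0.  This keeps the field's
        # dynamic range wide instead of letting a single peak compress it.
        lo = np.percentile(field[lung], 5)
        hi = np.percentile(field[lung], 75)
        field[lung] = np.clip((field[lung] - lo) / (hi - lo), 0.0, 1.0)
    return ImageVolume(
        data=field.astype(np.float32),
        spacing=(spec.spacing_mm,) * 3,
        units="normalized",
    )


def generate_ct_pair(
    spec: PhantomSpec, vent: ImageVolume, rng: np.random.Generator
) -> CTVolumePair:
    """Exhale/inhale HU pair: inhale = exhale - beta * vent inside the lung.

    The exhale lung carries a smooth texture so it is not flat; both phases
    get independent additive Gaussian acquisition noise (sigma ~ 10 HU).
    """
    body, lung, tumor = _body_and_lung_masks(spec)
    exhale = np.full(spec.grid_shape, spec.air_hu, dtype=np.float64)
    exhale[body] = spec.body_hu
    texture = ndimage.gaussian_filter(
        rng.standard_normal(spec.grid_shape), sigma=8.0 / spec.spacing_mm
    )
    if texture.std() > 0:
        texture = texture / texture.std() * spec.lung_texture_hu
    exhale[lung] = spec.base_lung_hu + texture[lung]
    if spec.tumor is not None:
        exhale[tumor] = spec.tumor[2]
    inhale = exhale.copy()
    inhale[lung] -= spec.beta_hu_per_vent * np.asarray(vent.data, dtype=np.float64)[lung]
    if spec.ct_noise_hu > 0:
        exhale = exhale + rng.normal(0, spec.ct_noise_hu, spec.grid_shape)
        inhale = inhale + rng.normal(0, spec.ct_noise_hu, spec.grid_shape)
    sp = (spec.spacing_mm,) * 3
    return CTVolumePair(
        exhale=ImageVolume(exhale.astype(np.float32), sp, units="HU"),
        inhale=ImageVolume(inhale.astype(np.float32), sp, units="HU"),
    )


def generate_pet_like(
    vent: ImageVolume, spec: PhantomSpec, rng: np.random.Generator
) -> ImageVolume:
    """Ventilation seen through a PET-like detector.

    activity = scale * vent convolved with a Gaussian PSF, multiplied by
    log-normal noise, plus ``n_hotspots`` single-voxel clumping spikes at
    ``hotspot_multiplier`` times the 99th-percentile lung activity.
    """
    _, lung, _ = _body_and_lung_masks(spec)
    act = spec.pet_scale_kbq * np.asarray(vent.data, dtype=np.float64)
    if spec.pet_psf_sigma_mm > 0:
        act = ndimage.gaussian_filter(act, sigma=spec.pet_psf_sigma_mm / spec.spacing_mm)
    if spec.pet_noise_scale > 0:
        act *= np.exp(rng.normal(0.0, spec.pet_noise_scale, act.shape))
    if spec.n_hotspots > 0 and lung.any():
        p99 = np.percentile(act[lung], 99)
        if p99 <= 0:
            p99 = max(act.max(), 1.0)
        lung_idx = np.argwhere(lung)
        picks = rng.choice(len(lung_idx), size=spec.n_hotspots, replace=False)
        for i in picks:
            z, y, x = lung_idx[i]
            act[z, y, x] = spec.hotspot_multiplier * p99
    return ImageVolume(
        data=act.astype(np.float32),
        spacing=(spec.spacing_mm,) * 3,
        units="kBq_per_mL",
    )


def generate_case(spec: PhantomSpec, case_id: str = "case_000") -> PhantomCase:
    """One fully generated phantom patient from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    _, lung, _ = _body_and_lung_masks(spec)
    vent = generate_ventilation_field(spec, rng)
    pair = generate_ct_pair(spec, vent, rng)
    pet = generate_pet_like(vent, spec, rng)
    return PhantomCase(
        pair=pair,
        true_vent=vent,
        pet_like=pet,
        true_lung=LungMask(lung, source="exhale"),
        case_id=case_id,
        seed=spec.seed,
        spec=spec,
    )


def check_case_invariants(case: PhantomCase) -> None:
    """Raise if a generated case violates the generator's guarantees.

    The inhale <= exhale check allows for the independent acquisition noise
    of the two phases (6 sigma of the noise difference); pre-noise the
    relation is exact by construction.
    """
    vent = np.asarray(case.true_vent.data)
    lung = case.true_lung.data
    if vent.min() < 0 or vent.max() > 1 + 1e-6:
        raise ParameterError("true_vent outside [0, 1]")
    if np.abs(vent[~lung]).max(initial=0.0) > 0:
        raise ParameterError("true_vent nonzero outside the lung")
    noise = case.spec.ct_noise_hu if case.spec is not None else 10.0
    tol = 6.0 * np.sqrt(2.0) * noise
    sel = lung & (vent > 0)
    if sel.any():
        diff = case.pair.inhale.data[sel] - case.pair.exhale.data[sel]
        if diff.max() > tol:
            raise ParameterError("inhale HU exceeds exhale HU beyond noise allowance")


def generate_cohort(
    n_cases: int,
    template: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with jittered geometry and ventilation.

    Per-case seeds derive from the master seed via numpy's SeedSequence, so
    cohorts are reproducible and any single case can be regenerated alone.
    """
    if n_cases < 1:
        raise ParameterError("n_cases must be >= 1")
    if template is None:
        template = PhantomSpec()
    out = []
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_cases)
    for i, child in enumerate(children):
        case_seed = int(child.generate_state(1)[0] % (2**31))
        jit = np.random.default_rng(case_seed)
        scale = jit.uniform(0.9, 1.1)
        lung_axes = tuple(
            tuple(a * jit.uniform(0.92, 1.08) for a in axes)
            for axes in template.lung_axes_mm
        )
        lung_centers = tuple(
            tuple(c + jit.uniform(-5.0, 5.0) for c in ctr)
            for ctr in template.lung_centers_mm
        )
        tumor = template.tumor
        if tumor is None and jit.uniform() < 0.5:
            # small solid lesion inside a random lung
            which = jit.integers(len(lung_centers))
            ctr = lung_centers[which]
            tumor_ctr = tuple(c + jit.uniform(-8, 8) for c in ctr)
            tumor = (tumor_ctr, float(jit.uniform(8.0, 12.0)), 20.0)
        spec = dataclasses.replace(
            template,
            body_axes_mm=tuple(a * scale for a in template.body_axes_mm),
            lung_axes_mm=lung_axes,
            lung_centers_mm=lung_centers,
            vent_blob_count=int(max(1, template.vent_blob_count + jit.integers(-2, 3))),
            vent_anterior_bias=float(
                np.clip(template.vent_anterior_bias + jit.uniform(-0.15, 0.15), 0, 1)
            ),
            tumor=tumor,
            seed=case_seed,
        )
        case = generate_case(spec, case_id=f"case_{i:03d}")
        check_case_invariants(case)
        out.append(case)
    return out


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)

    def conv(x):
        if isinstance(x, (tuple, list)):
            return [conv(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x

    return {k: conv(v) for k, v in d.items()}


def save_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    """Write per-case NIfTI volumes plus a JSON cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"n_cases": len(cases), "cases": []}
    for case in cases:
        cdir = out_dir / case.case_id
        cdir.mkdir(exist_ok=True)
        write_volume(case.pair.exhale, cdir / "exhale.nii.gz")
        write_volume(case.pair.inhale, cdir / "inhale.nii.gz")
        write_volume(case.pet_like, cdir / "pet.nii.gz")
        write_volume(case.true_vent, cdir / "true_vent.nii.gz")
        write_volume(
            ImageVolume(case.true_lung.data.astype(np.uint8),
                        case.true_vent.spacing, units="boolean"),
            cdir / "true_lung.nii.gz",
        )
        manifest["cases"].append({
            "case_id": case.case_id,
            "seed": case.seed,
            "spec": _spec_to_jsonable(case.spec) if case.spec else None,
        })
    path = out_dir / "cohort.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
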