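"""Quantitative CTVI evaluation: masked Spearman correlation and Dice
overlap of equal-volume functional-lung regions.

The lung (defined by the exhale-phase mask) is split into three
equal-volume regions by ranking voxel ventilation values: low (LFL),
medium (MFL) and high functioning lung (HFL).  The regions are computed
independently for the CTVI and the reference image, and the Dice similarity
coefficient DSC = 2TP / (2TP + FP + FN) is reported per region plus their
mean.  Both metrics depend only on voxel ranks, so they are invariant under
any strictly increasing transform of tie-free inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCaseError, ParameterError
from .image_io import ImageVolume
from .preprocessing import LungMask

#: Integer labels of the functional regions inside the mask.
LFL, MFL, HFL = 0, 1, 2
OUTSIDE = -1


@dataclass
class FunctionalSegmentation:
    """Equal-volume functional-lung labels: 0=LFL, 1=MFL, 2=HFL, -1 outside."""

    labels: np.ndarray
    thresholds: tuple[float, float]


@dataclass
class EvaluationReport:
    """Per-case metrics comparing a CTVI with a reference ventilation image."""

    case_id: str
    spearman: float
    dsc_hfl: float
    dsc_mfl: float
    dsc_lfl: float

    @property
    def dsc_avg(self) -> float:
        return (self.dsc_hfl + self.dsc_mfl + self.dsc_lfl) / 3.0

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "spearman": self.spearman,
            "dsc_hfl": self.dsc_hfl,
            "dsc_mfl": self.dsc_mfl,
            "dsc_lfl": self.dsc_lfl,
            "dsc_avg": self.dsc_avg,
        }


def _masked_values(vol: ImageVolume | np.ndarray, mask: LungMask) -> np.ndarray:
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)
    if tuple(data.shape) != tuple(mask.shape):
        raise ParameterError("volume and mask shapes differ")
    return np.asarray(data)[mask.data]


def spearman_masked(
    a: ImageVolume | np.ndarray, b: ImageVolume | np.ndarray, mask: LungMask
) -> float:
    """Spearman rank correlation over masked voxels (average ranks for ties)."""
    if mask.n_voxels == 0:
        raise ParameterError("mask is empty")
    va = _masked_values(a, mask).astype(np.float64)
    vb = _masked_values(b, mask).astype(np.float64)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DegenerateCaseError(
            "Spearman correlation undefined: constant input over the mask"
        )
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)


def equal_volume_tertiles(
    vent: ImageVolume | np.ndarray, mask: LungMask
) -> FunctionalSegmentation:
    """Split the masked voxels into three equal-count regions by value.

    Voxels are ranked ascending with ties broken by the stable linear voxel
    index; region sizes are N//3 each, with the remainder r = N mod 3
    distributed to the lowest regions first (LFL, then MFL).  Thresholds are
    the values at the LFL/MFL and MFL/HFL boundaries.
    """
    vals = _masked_values(vent, mask).astype(np.float64)
    n = vals.size
    if n < 3:
        raise DegenerateCaseError(f"cannot split {n} voxels into tertiles")
    order = np.argsort(vals, kind="stable")
    base, r = divmod(n, 3)
    sizes = [base + (1 if i < r else 0) for i in range(3)]
    region_of_rank = np.repeat([LFL, MFL, HFL], sizes)
    flat_labels = np.empty(n, dtype=np.int64)
    flat_labels[order] = region_of_rank
    labels = np.full(mask.shape, OUTSIDE, dtype=np.int64)
    labels[mask.data] = flat_labels
    t1 = float(vals[order[sizes[0] - 1]])
    t2 = float(vals[order[sizes[0] + sizes[1] - 1]])
    return FunctionalSegmentation(labels=labels, thresholds=(t1, t2))


def dice_coefficient(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """DSC = 2TP / (2TP + FP + FN) between two boolean regions.

    Both regions empty -> 1.0 (perfect agreement about absence).
    """
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("regions are not on the same grid")
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(b & ~a))
    fn = int(np.count_nonzero(a & ~b))
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def evaluate_case(
    ctvi: ImageVolume | np.ndarray,
    reference: ImageVolume | np.ndarray,
    exhale_mask: LungMask,
    case_id: str = "<unnamed>",
) -> EvaluationReport:
    """Masked Spearman plus per-region DSC between CTVI and reference.

    The tertile segmentations are computed independently for each image
    within the same exhale lung mask.
    """
    rho = spearman_masked(ctvi, reference, exhale_mask)
    seg_a = equal_volume_tertiles(reference, exhale_mask)
    seg_b = equal_volume_tertiles(ctvi, exhale_mask)
    dsc = {
        region: dice_coefficient(seg_a.labels == region, seg_b.labels == region)
        for region in (HFL, MFL, LFL)
    }
    return EvaluationReport(
        case_id=case_id,
        spearman=rho,
        dsc_hfl=dsc[HFL],
        dsc_mfl=dsc[MFL],
        dsc_lfl=dsc[LFL],
    )


#: Row order mirroring the published results table.
SUMMARY_ROWS = (
    ("Spearman correlation", "spearman"),
    ("DSC high functioning lung", "dsc_hfl"),
    ("DSC medium functioning lung", "dsc_mfl"),
    ("DSC low functioning lung", "dsc_lfl"),
    ("DSC average", "dsc_avg"),
)


def aggregate_reports(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Cohort summary: mean and sample (n-1) standard deviation per metric."""
    if not reports:
        raise ParameterError("no reports to aggregate")
    df = pd.DataFrame([r.as_dict() for r in reports])
    rows = []
    for label, col in SUMMARY_ROWS:
        vals = df[col].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"metric": label, "mean": float(vals.mean()), "sd": sd,
                     "n": len(vals)})
    return pd.DataFrame(rows)


def write_summary_csv(reports: list[EvaluationReport], path: str | Path) -> Path:
    path = Path(path)
    aggregate_reports(reports).to_csv(path, index=False)
    return path
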