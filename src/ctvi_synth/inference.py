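"""Slice-wise prediction of a full 3D CT ventilation image (CTVI).

Each axial slice of a preprocessed case is predicted independently by the
2D network, the slices are re-assembled in z order by explicit index
bookkeeping, and the volume is min-max normalized globally so the final
CTVI spans [0, 1].  The global rescale is monotone, so rank-based metrics
(Spearman, equal-volume functional regions) are unaffected by it.  No
post-prediction smoothing or filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ParameterError
from .image_io import ImageVolume
from .nn import UNet
from .preprocessing import PreprocessedCase


@dataclass
class CTVIResult:
    """A predicted ventilation volume with its provenance."""

    ctvi: ImageVolume
    case_id: str
    fold_id: int | None = None
    model_checkpoint_ref: str | None = None


def predict_volume(
    model: UNet,
    case: PreprocessedCase,
    batch_size: int = 16,
    fold_id: int | None = None,
    checkpoint_ref: str | None = None,
) -> CTVIResult:
    """Predict every axial slice, stack in z order, normalize globally."""
    x = np.moveaxis(case.channels, 0, 1)  # (z, 3, H, W)
    nz = x.shape[0]
    model.check_input_shape(x.shape[2], x.shape[3])
    out = np.empty((nz,) + x.shape[2:], dtype=np.float32)
    for start in range(0, nz, batch_size):
        batch = x[start : start + batch_size]
        pred = model.forward(batch, train=False)
        out[start : start + len(batch)] = pred[:, 0]
    lo, hi = float(out.min()), float(out.max())
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    vol = ImageVolume(out.astype(np.float32), spacing=(1.0, 1.0, 1.0),
                      units="normalized")
    return CTVIResult(ctvi=vol, case_id=case.case_id, fold_id=fold_id,
                      model_checkpoint_ref=checkpoint_ref)


def render_orthogonal_views(
    result: CTVIResult,
    reference: ImageVolume,
    out_dir: str | Path,
) -> list[Path]:
    """Write mid-plane axial/coronal/sagittal PNGs of CTVI and reference.

    Six files per case, all on the shared [0, 1] color scale.
    """
    if tuple(result.ctvi.shape) != tuple(reference.shape):
        raise ParameterError("CTVI and reference grids differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes = {"ctvi": np.asarray(result.ctvi.data),
               "reference": np.asarray(reference.data)}
    nz, ny, nx = result.ctvi.shape
    planes = {
        "axial": lambda v: v[nz // 2],
        "coronal": lambda v: v[:, ny // 2, :],
        "sagittal": lambda v: v[:, :, nx // 2],
    }
    written = []
    for vname, vol in volumes.items():
        for pname, cut in planes.items():
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(cut(vol), vmin=0.0, vmax=1.0, cmap="inferno",
                      origin="lower")
            ax.set_title(f"{result.case_id} {vname} {pname}")
            ax.axis("off")
            path = out_dir / f"{result.case_id}_{vname}_{pname}.png"
            fig.savefig(path, dpi=100, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
    return written
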