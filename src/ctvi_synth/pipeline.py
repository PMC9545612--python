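"""End-to-end experiment orchestration.

One seeded YAML config drives the full workflow: phantom cohort generation,
preprocessing, cross-validated training, slice-wise inference, and
evaluation.  A single master seed fans out to per-stage seeds through a
documented counter scheme (numpy SeedSequence entropy = [master, offset]),
so any stage can be replayed in isolation, and the run manifest alone
suffices to reproduce the experiment.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .errors import CtviError, DataError
from .evaluation import EvaluationReport, evaluate_case, write_summary_csv
from .image_io import ImageVolume
from .inference import predict_volume, render_orthogonal_views
from .model import NetworkConfig, TrainConfig, make_folds, train_fold
from .phantom import PhantomSpec, generate_cohort
from .preprocessing import compute_lung_mask, crop_or_pad, preprocess_case

log = logging.getLogger(__name__)

#: Fixed offsets of the seed fan-out: stage seed i = SeedSequence([master, i]).
STAGE_OFFSETS = {
    "phantom": 1,
    "folds": 2,
    "training": 3,
    "weights": 4,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the deterministic sub-seed of a named pipeline stage."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


DEFAULT_CONFIG = {
    "seed": 0,
    "n_cases": 6,
    "n_folds": 3,
    "phantom": {"grid_shape": [40, 64, 64], "spacing_mm": 4.0},
    "preprocess": {
        "target_spacing_mm": 4.0,
        "crop_shape": [40, 64, 64],
        "shift_mm": [0.0, 0.0, 0.0],
        "hu_threshold": -500.0,
        "closing_radius_vox": 1,
        "min_component_vox": 100,
        "sigma_clip_k": 4.0,
    },
    "network": {"base_filters": 8, "depth": 3},
    "train": {
        "alpha": 1.5,
        "gamma": 5.0,
        # a test-scale fold holds ~144 slices (~18 optimizer steps/epoch),
        # orders of magnitude fewer steps than clinical stacks provide, so
        # training runs to the learning-curve plateau (~60 epochs) instead
        # of the clinical-scale 15
        "epochs": 60,
        "learning_rate": 0.0003,
        "batch_size": 8,
        "max_rotation_deg": 10.0,
        "max_translation_px": 4,
        "val_fraction": 0.10,
        "augment": True,
    },
    "render_views": False,
}


def _merged_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return _merged_config(yaml.safe_load(fh) or {})


def _preprocess_phantom_case(case, pp_cfg: dict):
    return preprocess_case(
        case.pair,
        case.pet_like,
        case_id=case.case_id,
        target_spacing_mm=pp_cfg["target_spacing_mm"],
        crop_shape=tuple(pp_cfg["crop_shape"]),
        shift_mm=tuple(pp_cfg["shift_mm"]),
        hu_threshold=pp_cfg["hu_threshold"],
        closing_radius_vox=pp_cfg["closing_radius_vox"],
        min_component_vox=pp_cfg["min_component_vox"],
        sigma_clip_k=pp_cfg["sigma_clip_k"],
    )


def _crop_truth(case, pp_cfg: dict) -> ImageVolume:
    """True ventilation on the same crop window as the preprocessed case."""
    m_ex = compute_lung_mask(case.pair.exhale, pp_cfg["hu_threshold"],
                             pp_cfg["closing_radius_vox"],
                             pp_cfg["min_component_vox"], case.case_id, "exhale")
    m_in = compute_lung_mask(case.pair.inhale, pp_cfg["hu_threshold"],
                             pp_cfg["closing_radius_vox"],
                             pp_cfg["min_component_vox"], case.case_id, "inhale")
    from .preprocessing import union_mask

    m_u = union_mask(m_ex, m_in)
    return crop_or_pad(case.true_vent, tuple(pp_cfg["crop_shape"]), mask=m_u)


def run_experiment(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "runs/run",
) -> dict:
    """Run phantom -> preprocess -> k-fold train -> predict -> evaluate.

    Returns the run manifest (also written to ``out_dir/manifest.json``).
    Any stage failure raises with the stage name and case id; artifacts
    written before the failure are retained for debugging.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merged_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    seeds = {name: stage_seed(master, name) for name in STAGE_OFFSETS}
    manifest: dict = {
        "run_id": out_dir.name,
        "config": cfg,
        "master_seed": master,
        "stage_seeds": seeds,
        "stages": {},
        "wall_time_s": {},
    }

    def _timed(stage: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["wall_time_s"][stage] = round(
                    time.perf_counter() - self.t0, 3
                )

        return _T()

    # --- phantom cohort -------------------------------------------------
    with _timed("phantom"):
        ph = cfg["phantom"]
        template = PhantomSpec(
            grid_shape=tuple(ph["grid_shape"]), spacing_mm=ph["spacing_mm"]
        )
        try:
            cases = generate_cohort(cfg["n_cases"], template, seeds["phantom"])
        except CtviError as exc:
            raise DataError(f"stage phantom failed: {exc}") from exc
    log.info("generated %d phantom cases", len(cases))

    # --- preprocessing ---------------------------------------------------
    with _timed("preprocess"):
        pp_cfg = cfg["preprocess"]
        prepped = {}
        truths = {}
        for case in cases:
            try:
                prepped[case.case_id] = _preprocess_phantom_case(case, pp_cfg)
                truths[case.case_id] = _crop_truth(case, pp_cfg)
            except CtviError as exc:
                raise DataError(
                    f"stage preprocess failed on {case.case_id}: {exc}"
                ) from exc

    # --- folds -----------------------------------------------------------
    case_ids = [c.case_id for c in cases]
    folds = make_folds(case_ids, n_folds=cfg["n_folds"], seed=seeds["folds"])
    manifest["folds"] = [
        {"fold_id": f.fold_id, "train": f.train_case_ids, "test": f.test_case_ids}
        for f in folds
    ]

    # --- train / predict / evaluate per fold ------------------------------
    net_cfg = NetworkConfig(seed=seeds["weights"], **cfg["network"])
    reports: list[EvaluationReport] = []
    recovery: list[EvaluationReport] = []
    manifest["stages"]["folds"] = []
    for fold in folds:
        fold_dir = out_dir / f"fold_{fold.fold_id}"
        fold_dir.mkdir(exist_ok=True)
        train_cfg = TrainConfig(
            seed=int(
                np.random.SeedSequence(
                    [seeds["training"], fold.fold_id]
                ).generate_state(1)[0]
                % (2**31)
            ),
            **cfg["train"],
        )
        with _timed(f"train_fold_{fold.fold_id}"):
            try:
                model, hist = train_fold(fold, prepped, net_cfg, train_cfg)
            except CtviError as exc:
                raise DataError(
                    f"stage train failed on fold {fold.fold_id}: {exc}"
                ) from exc
        ckpt = fold_dir / "weights.npz"
        model.save(ckpt)
        hist_rows = ["epoch,train_loss,val_loss"] + [
            f"{e},{t},{v}"
            for e, t, v in zip(hist.epochs, hist.train_loss, hist.val_loss)
        ]
        (fold_dir / "history.csv").write_text("\n".join(hist_rows) + "\n")

        fold_entry = {"fold_id": fold.fold_id, "checkpoint": str(ckpt),
                      "cases": []}
        for cid in fold.test_case_ids:
            case = prepped[cid]
            result = predict_volume(model, case, fold_id=fold.fold_id,
                                    checkpoint_ref=str(ckpt))
            rep = evaluate_case(result.ctvi, case.label, case.exhale_mask,
                                case_id=cid)
            rec = evaluate_case(result.ctvi, truths[cid], case.exhale_mask,
                                case_id=cid)
            reports.append(rep)
            recovery.append(rec)
            report_path = fold_dir / f"{cid}_report.json"
            report_path.write_text(json.dumps(
                {"vs_label": rep.as_dict(), "vs_truth": rec.as_dict(),
                 "fold_id": fold.fold_id}, indent=2))
            fold_entry["cases"].append(
                {"case_id": cid, "report": str(report_path)}
            )
            if cfg.get("render_views"):
                label_vol = ImageVolume(case.label, (1.0, 1.0, 1.0),
                                        units="normalized")
                render_orthogonal_views(result, label_vol, fold_dir / "views")
        manifest["stages"]["folds"].append(fold_entry)

    # --- cohort summary ----------------------------------------------------
    summary_path = out_dir / "summary.csv"
    write_summary_csv(reports, summary_path)
    recovery_path = out_dir / "summary_vs_truth.csv"
    write_summary_csv(recovery, recovery_path)
    manifest["summary_csv"] = str(summary_path)
    manifest["summary_vs_truth_csv"] = str(recovery_path)
    manifest["reports"] = [r.as_dict() for r in reports]
    manifest["reports_vs_truth"] = [r.as_dict() for r in recovery]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-execute an experiment from its manifest's config snapshot."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_experiment(manifest["config"], out_dir)


def audit_manifest(manifest: dict) -> list[str]:
    """Cross-check the manifest for train/test leakage.

    Returns a list of human-readable violations (empty = clean): a test case
    appearing in its own fold's training list, or a report referencing a
    fold whose training set contains the reported case.
    """
    violations = []
    folds = {f["fold_id"]: f for f in manifest.get("folds", [])}
    for f in folds.values():
        overlap = set(f["train"]) & set(f["test"])
        if overlap:
            violations.append(
                f"fold {f['fold_id']}: cases {sorted(overlap)} in both train and test"
            )
    for entry in manifest.get("stages", {}).get("folds", []):
        fold = folds.get(entry["fold_id"])
        if fold is None:
            violations.append(f"report fold {entry['fold_id']} missing from folds")
            continue
        for case in entry["cases"]:
            if case["case_id"] in fold["train"]:
                violations.append(
                    f"case {case['case_id']} evaluated by a model trained on it "
                    f"(fold {entry['fold_id']})"
                )
            if case["case_id"] not in fold["test"]:
                violations.append(
                    f"case {case['case_id']} not in fold {entry['fold_id']} test list"
                )
    return violations
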