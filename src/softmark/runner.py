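"""End-to-end orchestration: simulate -> QC -> split -> augment -> train ->
evaluate -> equivalence, with per-stage count logging and a report renderer.

Outputs written to the run directory:

* ``config.yaml`` — the archived run configuration
* ``split.tsv`` — subject-id to set assignment
* ``run_manifest.json`` — seeds, per-stage counts, output file list
* per view: ``models/<view>/`` (weights, history), ``errors_<view>.csv``,
  ``summary_<view>.csv`` (landmark, n, mean error mm, p),
  ``ced_<view>.csv``, ``metrics.json``, ``equivalence.json``
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import synthetic
from .config import RunConfig
from .equivalence import bland_altman, icc_by_landmark, tost_equivalence
from .metrics import (
    ScaleCalibration,
    compute_ced,
    effective_scale,
    per_landmark_errors,
    scale_consistency,
    significance_vs_zero,
)
from .model import LandmarkCNN, train_model
from .pipeline import (
    assert_no_leakage,
    augment_training_set,
    filter_subjects,
    filter_view,
    resize_normalize,
    subject_split,
)
from .schemas import quality_control
from .synthetic import AnnotatorModel, simulate_annotator

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _simulate_annotation_rounds(cohort, cfg: RunConfig):
    """Two simulated manual annotation rounds on a random image subset.

    Emulates the intra-observer protocol: the annotator re-marks a
    random subset (default 20 images) after an interval; both rounds are
    jittered independently around the ground truth.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.master_seed, spawn_key=(901,)))
    k = min(cfg.icc_subset_size, len(cohort))
    subset = [cohort[i] for i in sorted(rng.choice(len(cohort), size=k,
                                                   replace=False))]
    rows = []
    for view in cfg.views:
        view_imgs = [im for im in subset if im.view == view]
        if len(view_imgs) < 2:
            continue
        r1, r2 = [], []
        for j, im in enumerate(view_imgs):
            seed1 = int(rng.integers(0, 2 ** 31 - 1))
            seed2 = int(rng.integers(0, 2 ** 31 - 1))
            model1 = AnnotatorModel(cfg.jitter_sd_mm, rng_seed=seed1)
            model2 = AnnotatorModel(cfg.jitter_sd_mm, rng_seed=seed2)
            r1.append(simulate_annotator(im.landmarks, model1,
                                         cfg.base_scale_mm_per_px))
            r2.append(simulate_annotator(im.landmarks, model2,
                                         cfg.base_scale_mm_per_px))
        df = icc_by_landmark(r1, r2, view, cfg.base_scale_mm_per_px)
        df.insert(0, "view", view)
        df["n_images"] = len(view_imgs)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@_stage("evaluate")
def evaluate_view(model: LandmarkCNN, test_images, cfg: RunConfig):
    """Predict on held-out images and compute the full metric set."""
    samples = [resize_normalize(im) for im in test_images]
    preds = model.predict_samples(samples)
    cal = ScaleCalibration(cfg.base_scale_mm_per_px)
    table, summary = per_landmark_errors(test_images, preds, cal)
    sig = significance_vs_zero(table)
    summary = summary.merge(sig[["landmark", "t_statistic", "p_value"]],
                            on="landmark")
    errors = table["error_mm"].to_numpy()
    ced = compute_ced(errors)
    tost = tost_equivalence(errors, cfg.equivalence)
    ba = bland_altman(errors, cfg.equivalence)
    return {
        "table": table,
        "summary": summary,
        "ced": ced,
        "tost": tost,
        "bland_altman": ba,
        "mean_error_mm": float(errors.mean()),
        "sd_error_mm": float(errors.std(ddof=1)),
    }


def run_pipeline(cfg: RunConfig, out_dir: str | os.PathLike,
                 verbose: int = 0) -> dict:
    """Run the full study pipeline on the synthetic cohort.

    Returns the in-memory results dict and writes all artifacts to
    ``out_dir``.  Deterministic under a fixed config: inference and
    metrics exactly, training within platform floating-point behaviour.
    """
    os.makedirs(out_dir, exist_ok=True)
    out_dir = os.fspath(out_dir)
    manifest: dict = {"seeds": {"master": cfg.master_seed,
                                "split": cfg.split_seed,
                                "augmentation": cfg.augmentation.seed,
                                "data": cfg.train.data_seed,
                                "init": cfg.train.init_seed},
                      "counts": {}, "outputs": []}
    cfg.save(os.path.join(out_dir, "config.yaml"))

    # -- simulate ----------------------------------------------------------
    try:
        cohort = synthetic.generate_cohort(cfg.n_subjects, cfg.master_seed,
                                           views=cfg.views)
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc
    logger.info("simulate: %d subjects -> %d images", cfg.n_subjects,
                len(cohort))
    manifest["counts"]["subjects"] = cfg.n_subjects
    manifest["counts"]["images"] = len(cohort)

    # -- quality control ---------------------------------------------------
    cohort, excluded = quality_control(cohort)
    if excluded:
        logger.info("qc: excluded subjects %s", sorted(excluded))
    manifest["counts"]["qc_excluded_subjects"] = len(excluded)
    subjects = sorted({im.subject_id for im in cohort})
    manifest["counts"]["qc_subjects"] = len(subjects)

    # -- split -------------------------------------------------------------
    try:
        split = subject_split(subjects, cfg.split_sizes, cfg.split_seed)
    except Exception as exc:
        raise StageError(f"stage 'split' failed: {exc}") from exc
    ok, problems = assert_no_leakage(split, cohort)
    if not ok:
        raise StageError(f"stage 'split' failed leakage check: {problems}")
    with open(os.path.join(out_dir, "split.tsv"), "w") as fh:
        fh.write("subject_id\tset\n")
        for name, ids in (("train", split.train_ids), ("val", split.val_ids),
                          ("test", split.test_ids)):
            for sid in ids:
                fh.write(f"{sid}\t{name}\n")
    logger.info("split: train/val/test subjects = %d/%d/%d",
                *map(len, (split.train_ids, split.val_ids, split.test_ids)))

    results: dict = {"views": {}, "split": split}
    scale_sample = None
    for view in cfg.views:
        view_imgs = filter_view(cohort, view)
        train_imgs = filter_subjects(view_imgs, split.train_ids)
        val_imgs = filter_subjects(view_imgs, split.val_ids)
        test_imgs = filter_subjects(view_imgs, split.test_ids)

        # -- augment -------------------------------------------------------
        try:
            aug = augment_training_set(train_imgs, cfg.augmentation)
        except Exception as exc:
            raise StageError(f"stage 'augment' failed: {exc}") from exc
        logger.info("augment[%s]: %d original + %d augmented = %d images",
                    view, len(train_imgs), len(aug) - len(train_imgs),
                    len(aug))
        manifest["counts"][f"train_images_{view}"] = len(aug)
        manifest["counts"][f"val_images_{view}"] = len(val_imgs)
        manifest["counts"][f"test_images_{view}"] = len(test_imgs)

        # -- train ---------------------------------------------------------
        try:
            tr_s = [resize_normalize(im) for im in aug]
            va_s = [resize_normalize(im) for im in val_imgs]
            model = train_model(tr_s, va_s, view, cfg.train, verbose=verbose)
        except Exception as exc:
            raise StageError(f"stage 'train' failed: {exc}") from exc
        model.save(os.path.join(out_dir, "models", view))
        logger.info("train[%s]: best epoch %d, best val loss %.6f",
                    view, model.best_epoch_ + 1, model.best_val_loss_)

        # -- evaluate ------------------------------------------------------
        ev = evaluate_view(model, test_imgs, cfg)
        ev["table"].to_csv(os.path.join(out_dir, f"errors_{view}.csv"),
                           index=False)
        ev["summary"].to_csv(os.path.join(out_dir, f"summary_{view}.csv"),
                             index=False)
        pd.DataFrame({"threshold_mm": ev["ced"].thresholds,
                      "success_rate": ev["ced"].success_rates}
                     ).to_csv(os.path.join(out_dir, f"ced_{view}.csv"),
                              index=False)
        results["views"][view] = {"model": model, **ev}
        if scale_sample is None:
            scale_sample = [effective_scale(im.width) for im in view_imgs[:20]]

    # -- scale consistency and intra-observer repeatability ----------------
    sc = scale_consistency(scale_sample)
    icc_df = _simulate_annotation_rounds(cohort, cfg)
    icc_df.to_csv(os.path.join(out_dir, "icc_by_landmark.csv"), index=False)
    results["scale_consistency"] = sc
    results["icc"] = icc_df
    results["icc_mean"] = float(icc_df["icc"].mean())

    # -- metric/equivalence JSON blobs -------------------------------------
    metrics_blob = {
        "scale_consistency": asdict(sc),
        "icc_mean": results["icc_mean"],
        "views": {},
    }
    equiv_blob = {}
    for view, ev in results["views"].items():
        metrics_blob["views"][view] = {
            "mean_error_mm": ev["mean_error_mm"],
            "sd_error_mm": ev["sd_error_mm"],
            "success_rates": dict(zip(map(str, ev["ced"].thresholds),
                                      ev["ced"].success_rates)),
            "auc_ced": ev["ced"].auc_ced,
            "best_epoch": ev["model"].best_epoch_ + 1,
        }
        equiv_blob[view] = {
            "mean_error_mm": ev["mean_error_mm"],
            "sd_error_mm": ev["sd_error_mm"],
            "tost": asdict(ev["tost"]),
            "bland_altman": asdict(ev["bland_altman"]),
        }
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics_blob, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "equivalence.json"), "w") as fh:
        json.dump(equiv_blob, fh, indent=2, sort_keys=True)

    manifest["outputs"] = sorted(
        os.path.relpath(os.path.join(root, f), out_dir)
        for root, _, files in os.walk(out_dir) for f in files)
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def render_report(report_dir: str | os.PathLike) -> str:
    """Render a completed run as human-readable markdown tables.

    Produces the per-landmark error tables (one per view), the
    success-rate/AUC-CED table and the equivalence table, plus pointers
    to the CED and per-row error (Bland-Altman) plot data.
    """
    report_dir = os.fspath(report_dir)
    mpath = os.path.join(report_dir, "metrics.json")
    epath = os.path.join(report_dir, "equivalence.json")
    if not (os.path.exists(mpath) and os.path.exists(epath)):
        raise FileNotFoundError(f"{report_dir} does not contain a completed "
                                "run (metrics.json / equivalence.json missing)")
    with open(mpath) as fh:
        metrics = json.load(fh)
    with open(epath) as fh:
        equiv = json.load(fh)

    lines = ["# Evaluation report", ""]
    for view in metrics["views"]:
        summary = pd.read_csv(os.path.join(report_dir, f"summary_{view}.csv"))
        lines += [f"## Per-landmark errors ({view} view)", "",
                  "| Landmark | n | Mean error (mm) | p-value |",
                  "|---|---|---|---|"]
        for _, row in summary.iterrows():
            lines.append(f"| {row.landmark} | {int(row.n)} | "
                         f"{row.mean_error_mm:.3f} | {row.p_value:.3g} |")
        lines.append("")

    lines += ["## Success rates and AUC-CED", "",
              "| Dataset | Mean error (mm) | "
              + " | ".join(f"SR@{t} mm" for t in (2.0, 2.5, 3.0, 4.0))
              + " | AUC-CED |", "|---|---|---|---|---|---|---|"]
    for view, m in metrics["views"].items():
        srs = " | ".join(f"{100 * m['success_rates'][str(t)]:.2f}%"
                         for t in (2.0, 2.5, 3.0, 4.0))
        lines.append(f"| {view} | {m['mean_error_mm']:.4f} | {srs} | "
                     f"{m['auc_ced']:.2f} |")
    lines.append("")

    lines += ["## Equivalence (TOST +/-2 mm) and Bland-Altman", "",
              "| Dataset | Mean (mm) | SD (mm) | TOST p | Bias (mm) | "
              "95% limits of agreement |", "|---|---|---|---|---|---|"]
    for view, e in equiv.items():
        ba = e["bland_altman"]
        lines.append(
            f"| {view} | {e['mean_error_mm']:.4f} | {e['sd_error_mm']:.4f} | "
            f"{e['tost']['p_tost']:.3g} | {ba['bias_mm']:.3f} | "
            f"{ba['loa_lower']:.3f} to {ba['loa_upper']:.3f} mm |")
    lines += ["",
              f"Mean intra-observer ICC(2,1): {metrics['icc_mean']:.3f}",
              "",
              "CED plot data: ced_<view>.csv; Bland-Altman plot data: "
              "errors_<view>.csv (per-row mm errors).", ""]
    text = "\n".join(lines)
    with open(os.path.join(report_dir, "report.md"), "w") as fh:
        fh.write(text)
    return text
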