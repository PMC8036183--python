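"""End-to-end orchestration: simulate -> SUVR -> per-axis CV -> vote ->
external test -> CAM, from one configuration mapping.

Every stochastic stage consumes a seed derived from the single top-level
seed, and the summary JSON records all of them together with per-stage wall
times and content hashes, so a rerun with the same configuration is
comparable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cam import compute_cam, render_overlay
from .cnn import CNNConfig, save_model
from .dataprep import (AXES, AugmentParams, Dataset, decompose,
                       normalize_intensity)
from .evaluate import (CVResult, Metrics, confusion_metrics, evaluate_external,
                       majority_vote, run_cv, select_best_axis,
                       stratified_kfold)
from .phantom import PhantomSpec, generate_cohort
from .suvr import apply_brain_mask, compute_suvr, extract_reference_tac

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full run (mirrors the YAML layout)."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_neg: int = 101
    n_pos: int = 32
    test_n_neg: int = 13
    test_n_pos: int = 9
    suvr_window_min: tuple[float, float] = (50.0, 70.0)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    augment: AugmentParams | None = None
    k: int = 5
    seed: int = 0
    axes: tuple[str, ...] = AXES
    render_cams: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "frame_schedule" in ph:
                ph["frame_schedule"] = [tuple(f) for f in ph["frame_schedule"]]
            kwargs["phantom"] = PhantomSpec(**ph)
        if "cnn" in raw:
            cn = dict(raw["cnn"])
            if "conv_filters" in cn:
                cn["conv_filters"] = tuple(cn["conv_filters"])
            kwargs["cnn"] = CNNConfig(**cn)
        if raw.get("augment"):
            kwargs["augment"] = AugmentParams(**raw["augment"])
        cohort = raw.get("cohort", {})
        for name in ("n_neg", "n_pos", "test_n_neg", "test_n_pos"):
            if name in cohort:
                kwargs[name] = int(cohort[name])
        cv = raw.get("cv", {})
        if "k" in cv:
            kwargs["k"] = int(cv["k"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "suvr_window_min" in raw:
            kwargs["suvr_window_min"] = tuple(raw["suvr_window_min"])
        if "axes" in raw:
            kwargs["axes"] = tuple(raw["axes"])
        if "render_cams" in raw:
            kwargs["render_cams"] = bool(raw["render_cams"])
        return cls(**kwargs)


def scans_to_suvr_datasets(
    scans, axes, window_min=(50.0, 70.0), normalize: bool = True,
) -> dict[str, Dataset]:
    """Quantify a phantom cohort and decompose it along the given axes.

    Per scan: reference TAC from the cerebellar grey-matter mask, SUVR over
    the window, brain masking with the grey+white templates, then slice
    decomposition and intensity normalization.
    """
    per_axis: dict[str, list] = {axis: [] for axis in axes}
    for scan in scans:
        tac = extract_reference_tac(scan.dynamic, scan.masks["cerebellar_gm"])
        img = compute_suvr(scan.dynamic, tac, window_min, scan_id=scan.scan_id)
        gm = scan.masks["cortical_gm"] | scan.masks["cerebellar_gm"]
        img = apply_brain_mask(img, gm, scan.masks["white_matter"])
        for axis in axes:
            stack = decompose(img, axis, label=scan.label)
            if normalize:
                stack = dc_replace(stack,
                                   planes=normalize_intensity(stack.planes))
            per_axis[axis].append((stack, scan.label))
    return {axis: Dataset(items=items) for axis, items in per_axis.items()}


def _combined_vote_result(
    results: dict[str, CVResult], labels: dict[str, int], k: int,
    threshold: float,
) -> dict:
    """Per-fold majority vote of the three axis models' held-out predictions."""
    if set(results) != set(AXES):
        raise ValueError("combined vote needs all three axes")
    fold_of = results[AXES[0]].fold_of
    fold_metrics: list[Metrics] = []
    for fold in range(k):
        ids = [sid for sid, f in fold_of.items() if f == fold]
        pred = [
            majority_vote(
                results["axial"].probabilities[sid],
                results["coronal"].probabilities[sid],
                results["sagittal"].probabilities[sid],
                threshold=threshold,
            )
            for sid in ids
        ]
        fold_metrics.append(confusion_metrics(pred, [labels[s] for s in ids]))
    agg = CVResult(fold_metrics=fold_metrics, probabilities={},
                   fold_of=fold_of, axis="combined")
    return agg.summary()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    The run directory contains the cohort manifest, per-axis CV results and
    fold models, the combined-vote metrics, external-test metrics, CAM
    overlays (when enabled) and ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    seeds = {
        "top_level": config.seed,
        "cohort_train": config.seed,
        "cohort_test": config.seed + 1,
        "folds": config.seed + 2,
        "cnn_base": config.cnn.rng_seed,
    }

    def stage(name):
        timings[name] = time.time() - t0
        logger.info("stage %s done at %.1fs", name, timings[name])

    try:
        train_scans = generate_cohort(config.phantom, config.n_neg,
                                      config.n_pos, seed=seeds["cohort_train"])
        test_scans = generate_cohort(config.phantom, config.test_n_neg,
                                     config.test_n_pos,
                                     seed=seeds["cohort_test"]) \
            if config.test_n_neg + config.test_n_pos > 0 else []
        for i, scan in enumerate(test_scans):
            scan.scan_id = f"test_{i:04d}"
        stage("simulate")
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        datasets = scans_to_suvr_datasets(train_scans, config.axes,
                                          config.suvr_window_min)
        test_sets = scans_to_suvr_datasets(test_scans, config.axes,
                                           config.suvr_window_min) \
            if test_scans else {}
        stage("suvr")
    except Exception as exc:
        raise RuntimeError(f"[suvr] {exc}") from exc

    labels = {s.scan_id: s.label for s in train_scans}
    manifest = [
        {"scan_id": s.scan_id, "label": s.label,
         "cortical_suvr": s.truth["cortical_gm"]}
        for s in train_scans + list(test_scans)
    ]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        folds = stratified_kfold(labels, k=config.k, rng_seed=seeds["folds"])
        results: dict[str, CVResult] = {}
        for axis in config.axes:
            results[axis] = run_cv(datasets[axis], axis, config.cnn, folds,
                                   augment_params=config.augment)
            for fold, model in enumerate(results[axis].models):
                save_model(model, out / f"model_{axis}_fold{fold}")
        stage("train_cv")
    except Exception as exc:
        raise RuntimeError(f"[train_cv] {exc}") from exc

    summary: dict[str, Any] = {
        "seeds": seeds,
        "config": {
            "k": config.k,
            "axes": list(config.axes),
            "cohort": [config.n_neg, config.n_pos,
                       config.test_n_neg, config.test_n_pos],
            "grid_shape": list(config.phantom.grid_shape),
            "cnn": asdict(config.cnn),
        },
        "cv": {axis: r.summary() for axis, r in results.items()},
    }

    try:
        if set(config.axes) == set(AXES):
            summary["cv"]["combined"] = _combined_vote_result(
                results, labels, config.k, config.cnn.decision_threshold)
        best = select_best_axis(results)
        summary["best_axis"] = best
        stage("vote")
    except Exception as exc:
        raise RuntimeError(f"[vote] {exc}") from exc

    try:
        if test_scans:
            metrics, probs = evaluate_external(
                results[best].models, test_sets[best],
                threshold=config.cnn.decision_threshold)
            summary["external_test"] = {
                "axis": best,
                "metrics": metrics.as_dict(),
                "mean_probability_true_positive": float(np.mean(
                    [probs[s.scan_id] for s in test_scans if s.label == 1]))
                if any(s.label == 1 for s in test_scans) else None,
            }
            with (out / "external_probabilities.csv").open("w") as fh:
                fh.write("scan_id,probability,label\n")
                for s in test_scans:
                    fh.write(f"{s.scan_id},{probs[s.scan_id]:.6f},{s.label}\n")
        stage("external_test")
    except Exception as exc:
        raise RuntimeError(f"[external_test] {exc}") from exc

    try:
        if config.render_cams and test_scans:
            model = results[best].models[0]
            for want in (0, 1):
                scan = next((s for s in test_scans if s.label == want), None)
                if scan is None:
                    continue
                ds = test_sets[best]
                stack = next(s for s, _ in ds.items
                             if s.scan_id == scan.scan_id)
                amap = compute_cam(model, stack)
                mid = stack.planes[stack.n_slices // 2]
                render_overlay(amap, mid,
                               out / f"cam_{scan.scan_id}_label{want}.png")
        stage("cam")
    except Exception as exc:
        raise RuntimeError(f"[cam] {exc}") from exc

    summary["timings_s"] = timings
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    summary["hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.json"))
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
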