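"""End-to-end orchestration: simulate -> split -> preprocess/augment ->
pretrain GAE -> train classifier -> train segmenters -> predict -> evaluate.

Stages are driven by a single :class:`~glioseg.config.PipelineConfig`;
ablation toggles replace disabled stages with documented pass-throughs (no
gate = always segment, no GAE = random-init encoders and no ROI, no ensemble
= single attention U-Net).  Every random draw derives from the global seed,
so two runs of the same config produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, derive_seed
from .detect import build_classifier, kmeans_latent, roi_from_clusters, train_classifier
from .errors import ConfigError
from .gae import build_gae, encode_image, pretrain_gae, reconstruction_mse
from .metrics import evaluate_dataset
from .phantom import LABEL_TUMOR, Sample, generate_dataset
from .preprocess import augment_pair, stratified_subject_split, zscore_normalize
from .segment import (EnsembleConfig, PipelineModels, UNet, build_residual_unet,
                      init_encoder_from_gae, predict_mask, train_segmenter)

__all__ = ["RunReport", "run_pipeline", "ablation_ladder", "LADDER"]

# the five progressively-enabled configurations of the ablation ladder
LADDER: list[tuple[str, dict]] = [
    ("unet_baseline", dict(use_gae_pretrain=False, use_attention=False,
                           use_kmeans_roi=False, use_gate=False, use_ensemble=False)),
    ("+gae", dict(use_gae_pretrain=True, use_attention=False,
                  use_kmeans_roi=False, use_gate=False, use_ensemble=False)),
    ("+gae+attention", dict(use_gae_pretrain=True, use_attention=True,
                            use_kmeans_roi=False, use_gate=False, use_ensemble=False)),
    ("+gae+attention+kmeans_roi", dict(use_gae_pretrain=True, use_attention=True,
                                       use_kmeans_roi=True, use_gate=False,
                                       use_ensemble=False)),
    ("full_ensemble", dict(use_gae_pretrain=True, use_attention=True,
                           use_kmeans_roi=True, use_gate=True, use_ensemble=True)),
]


@dataclass
class RunReport:
    metrics: dict
    member_test_dice: list[float]
    classifier: dict
    gae: dict
    config: dict
    global_seed: int
    stage_times: dict[str, float] = field(default_factory=dict)
    stage_subjects: dict[str, list[str]] = field(default_factory=dict)
    histories: dict[str, list[dict]] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True,
                                         default=float))


def _normalize_images(samples: list[Sample]) -> np.ndarray:
    return np.stack([zscore_normalize(s.image)[0] for s in samples])


def _labels(samples: list[Sample]) -> np.ndarray:
    return np.array([1 if s.label == LABEL_TUMOR else 0 for s in samples], dtype=int)


def _masks(samples: list[Sample]) -> np.ndarray:
    return np.stack([s.mask.astype(np.float64) for s in samples])


def _augment_split(samples: list[Sample], config: PipelineConfig) -> list[Sample]:
    """Append ``n_augment`` deterministic augmented copies per sample."""
    out = list(samples)
    for i, s in enumerate(samples):
        for j in range(config.n_augment):
            img, msk = augment_pair(s.image, s.mask, config.augmentation,
                                    draw_index=i * max(config.n_augment, 1) + j)
            label = LABEL_TUMOR if msk.any() else "non_tumor"
            out.append(Sample(image=img, mask=msk, subject_id=s.subject_id, label=label))
    return out


def _compute_rois(samples: list[Sample], images_norm: np.ndarray, gae_model,
                  config: PipelineConfig) -> tuple[np.ndarray, list[dict]]:
    rois = np.zeros((len(samples),) + samples[0].mask.shape, dtype=np.float64)
    seed = derive_seed(config.global_seed, "kmeans")
    diagnostics = []
    for i in range(len(samples)):
        latent = encode_image(gae_model, images_norm[i])
        clusters = kmeans_latent(latent, k=config.kmeans_k, seed=seed)
        rois[i] = roi_from_clusters(clusters, latent).mask
        diagnostics.append({"sample": i, "subject_id": samples[i].subject_id,
                            "inertia": clusters.inertia,
                            **{f"cluster{j}_size": int(s)
                               for j, s in enumerate(clusters.cluster_sizes())}})
    return rois, diagnostics


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> RunReport:
    """Execute every enabled stage in order and evaluate on the test split."""
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    times: dict[str, float] = {}
    stage_subjects: dict[str, list[str]] = {}
    histories: dict[str, list[dict]] = {}
    artifacts: dict[str, str] = {}

    def tic() -> float:
        return time.perf_counter()

    # -- simulate -----------------------------------------------------------
    t0 = tic()
    samples, manifest = generate_dataset(config.phantom)
    by_path = {row.path: samples[i] for i, row in enumerate(manifest.itertuples())}
    times["simulate"] = tic() - t0

    # -- split --------------------------------------------------------------
    t0 = tic()
    split = stratified_subject_split(manifest, config.split)
    split_samples = {name: [by_path[p] for p in getattr(split, name)["path"]]
                     for name in ("train", "val", "test")}
    for name in ("train", "val", "test"):
        stage_subjects[f"split_{name}"] = sorted(
            set(getattr(split, name)["subject_id"]))
    times["split"] = tic() - t0

    # -- preprocess / augment -----------------------------------------------
    t0 = tic()
    train_samples = _augment_split(split_samples["train"], config)
    val_samples = split_samples["val"]
    test_samples = split_samples["test"]
    x_train = _normalize_images(train_samples)
    x_val = _normalize_images(val_samples)
    y_train, y_val = _masks(train_samples), _masks(val_samples)
    times["preprocess"] = tic() - t0

    train_cfg = dataclasses.replace(config.train, seed=derive_seed(config.global_seed, "shuffle"))

    # -- phase 1: GAE pre-training ------------------------------------------
    gae_model = None
    gae_info: dict = {"enabled": bool(config.use_gae_pretrain)}
    if config.use_gae_pretrain:
        t0 = tic()
        gae_model = build_gae(config.gae, derive_seed(config.global_seed, "gae_init"),
                              image_size=config.phantom.image_size)
        gae_info["initial_mse"] = reconstruction_mse(gae_model, x_train)
        gae_model, hist = pretrain_gae(gae_model, x_train, train_cfg, val_images=x_val)
        gae_info["final_mse"] = reconstruction_mse(gae_model, x_train)
        gae_info["epochs_run"] = len(hist)
        histories["gae"] = hist
        stage_subjects["gae_pretrain"] = sorted(
            {s.subject_id for s in train_samples} | {s.subject_id for s in val_samples})
        times["pretrain_gae"] = tic() - t0

    # -- ROI masks for training (phase 2, unsupervised part) -----------------
    roi_mode = "mask_input_channel" if config.use_kmeans_roi else "off"
    roi_train = roi_val = None
    if config.use_kmeans_roi:
        t0 = tic()
        roi_train, roi_diag = _compute_rois(train_samples, x_train, gae_model, config)
        roi_val, _ = _compute_rois(val_samples, x_val, gae_model, config)
        if out is not None:
            pd.DataFrame(roi_diag).to_csv(out / "roi_cluster_diagnostics.csv",
                                          index=False, lineterminator="\n")
            artifacts["roi_diagnostics"] = str(out / "roi_cluster_diagnostics.csv")
        times["kmeans_roi"] = tic() - t0

    # -- phase 2: classifier --------------------------------------------------
    clf_model = None
    clf_info: dict = {"enabled": bool(config.use_gate)}
    if config.use_gate:
        t0 = tic()
        clf_model = build_classifier(config.classifier,
                                     derive_seed(config.global_seed, "clf_init"))
        clf_inputs = x_train
        clf_val_inputs = x_val
        if config.classifier.input_kind == "latent":
            if gae_model is None:
                raise ConfigError("latent classifier input requires use_gae_pretrain")
            clf_inputs = np.stack([
                encode_image(gae_model, im).grid.transpose(2, 0, 1) for im in x_train])
            clf_val_inputs = np.stack([
                encode_image(gae_model, im).grid.transpose(2, 0, 1) for im in x_val])
        clf_model, hist = train_classifier(
            clf_model, clf_inputs, _labels(train_samples), train_cfg,
            val_inputs=clf_val_inputs, val_labels=_labels(val_samples))
        histories["classifier"] = hist
        clf_info["epochs_run"] = len(hist)
        stage_subjects["classifier"] = stage_subjects.get("gae_pretrain") or sorted(
            {s.subject_id for s in train_samples} | {s.subject_id for s in val_samples})
        times["train_classifier"] = tic() - t0

    # -- phase 3: segmenters ---------------------------------------------------
    t0 = tic()
    seg_in_channels = config.segmenter.in_channels + (1 if roi_mode == "mask_input_channel" else 0)
    cfg_a = dataclasses.replace(config.segmenter, in_channels=seg_in_channels,
                                use_attention_gates=config.use_attention,
                                residual_encoder=False)
    member_a = UNet(cfg_a, derive_seed(config.global_seed, "seg_a_init"))
    if config.use_gae_pretrain:
        init_encoder_from_gae(member_a, gae_model)
    member_a, hist_a = train_segmenter(
        member_a, x_train, y_train, train_cfg, config.loss, roi_mode=roi_mode,
        rois=roi_train, val_images=x_val, val_masks=y_val, val_rois=roi_val)
    histories["segmenter_attention_unet"] = hist_a
    segmenters = [member_a]

    if config.use_ensemble:
        cfg_b = dataclasses.replace(config.segmenter, in_channels=seg_in_channels,
                                    use_attention_gates=False, residual_encoder=True)
        member_b = build_residual_unet(cfg_b, derive_seed(config.global_seed, "seg_b_init"))
        member_b, hist_b = train_segmenter(
            member_b, x_train, y_train, train_cfg, config.loss, roi_mode=roi_mode,
            rois=roi_train, val_images=x_val, val_masks=y_val, val_rois=roi_val)
        histories["segmenter_residual_unet"] = hist_b
        segmenters.append(member_b)
    stage_subjects["segmenter"] = sorted(
        {s.subject_id for s in train_samples} | {s.subject_id for s in val_samples})
    times["train_segmenters"] = tic() - t0

    # -- predict + evaluate on the held-out test split --------------------------
    t0 = tic()
    ens_cfg = (config.ensemble if len(segmenters) == len(config.ensemble.weights)
               else EnsembleConfig(weights=tuple([1.0 / len(segmenters)] * len(segmenters)),
                                   binarize_threshold=config.ensemble.binarize_threshold))
    models = PipelineModels(segmenters=segmenters, ensemble=ens_cfg, gae=gae_model,
                            classifier=clf_model, gate_tau=config.gate_tau,
                            use_gate=config.use_gate, roi_mode=roi_mode,
                            kmeans_k=config.kmeans_k,
                            kmeans_seed=derive_seed(config.global_seed, "kmeans"))
    stage_subjects["evaluate"] = sorted({s.subject_id for s in test_samples})

    preds, fused_maps, class_scores = [], [], []
    for s in test_samples:
        mask, fused, cprob, _roi = predict_mask(models, s.image)
        preds.append(mask)
        fused_maps.append(fused)
        if cprob is not None:
            class_scores.append(cprob.tumor_probability)

    labels_test = _labels(test_samples)
    truths = [s.mask for s in test_samples]
    report_metrics = evaluate_dataset(
        preds, truths,
        class_scores=class_scores if class_scores else None,
        class_labels=labels_test if class_scores else None)

    member_dice = []
    for i, member in enumerate(segmenters):
        solo = dataclasses.replace(
            models, segmenters=[member],
            ensemble=EnsembleConfig(weights=(1.0,),
                                    binarize_threshold=ens_cfg.binarize_threshold))
        solo_preds = [predict_mask(solo, s.image)[0] for s in test_samples]
        member_dice.append(evaluate_dataset(solo_preds, truths).dice)
    times["evaluate"] = tic() - t0

    if class_scores:
        clf_info["test_accuracy"] = report_metrics.accuracy
        clf_info["test_auc_roc"] = report_metrics.auc_roc

    report = RunReport(
        metrics=report_metrics.to_dict(), member_test_dice=member_dice,
        classifier=clf_info, gae=gae_info, config=config.to_dict(),
        global_seed=config.global_seed, stage_times=times,
        stage_subjects=stage_subjects, histories=histories, artifacts=artifacts,
    )
    if out is not None:
        report.to_json(out / "run_report.json")
        report_metrics.to_csv_row(out / "metrics.csv")
        artifacts["run_report"] = str(out / "run_report.json")
    return report


def ablation_ladder(config: PipelineConfig, output_dir: str | Path | None = None
                    ) -> tuple[pd.DataFrame, list[RunReport]]:
    """Run the five ladder configurations on identical data and seeds.

    Returns a table shaped like the ablation summary (configuration, dice,
    jaccard, sensitivity, hd95) plus the full per-row reports.
    """
    rows, reports = [], []
    for name, flags in LADDER:
        cfg = dataclasses.replace(config, **flags)
        report = run_pipeline(cfg)
        m = report.metrics
        rows.append({"configuration": name, "dice": m["dice"], "jaccard": m["jaccard"],
                     "sensitivity": m["sensitivity"], "hd95": m["hd95"]})
        reports.append(report)
    table = pd.DataFrame(rows, columns=["configuration", "dice", "jaccard",
                                        "sensitivity", "hd95"])
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ablation_ladder.csv", index=False, lineterminator="\n")
    return table, reports
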