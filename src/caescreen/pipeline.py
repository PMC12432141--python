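"""End-to-end orchestration: simulate -> preprocess -> train -> score ->
threshold -> classify -> evaluate.

Two entry points:

* :func:`run_pipeline` — the disk-based workflow behind the ``run`` CLI
  command: reads/writes TIFFs, CSVs and JSON sidecars, enforces that no
  image is both trained on and scored, and logs each stage.
* :func:`desk_scale_experiment` — the package's in-memory reference
  experiment: a seeded synthetic study (scaled-down autoencoder, 128x128
  inputs) that trains on clean simulated images and measures how well the
  IRE separates held-out clean from artifact-laden ones.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_seeds, substream
from .cae import CAE, CAEConfig, build_cae
from .errors import ValidationError
from .evaluate import bootstrap_auc, confusion_metrics, evaluate_dataset, ttest_ire
from .io import PipelineConfig, read_image, read_manifest
from .preprocess import preprocess
from .scoring import classify, dataset_threshold, score_images
from .synthetic import (ARTIFACT_KINDS, SceneSpec, default_artifact,
                        generate_dataset, generate_image)

log = logging.getLogger("caescreen")


def _setup_logging(out_dir: Path | None = None) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    if out_dir is not None:
        fh = logging.FileHandler(out_dir / "pipeline.log")
        fh.setFormatter(fmt)
        log.addHandler(fh)


def _load_preprocessed(paths, cfg: PipelineConfig) -> np.ndarray:
    imgs = []
    for p in paths:
        raw = read_image(p, bit_depth=cfg.bit_depth)
        imgs.append(preprocess(raw, kernel=cfg.blur_kernel, sigma=cfg.blur_sigma,
                               sd_mult=cfg.sd_mult, block=cfg.block,
                               bit_depth=cfg.bit_depth))
    return np.asarray(imgs, dtype=np.float32)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 manifest: pd.DataFrame | str | Path | None = None) -> dict:
    """Run the full workflow, writing all stage outputs under ``out_dir``.

    Training uses clean-labeled images (the first ``n_train_clean`` of
    them); every other image is scored. An image never appears in both
    roles. Returns a dict with the manifest split, scores, threshold,
    predicted labels and (when ground truth is available) the evaluation
    report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    config.to_yaml(out_dir / "pipeline.yaml")

    t0 = time.time()
    if manifest is None:
        if config.simulate is None:
            raise ValidationError("no manifest given and no simulate section in config")
        sim = dict(config.simulate)
        spec = SceneSpec(**sim.get("scene", {}))
        data_dir = out_dir / "data"
        log.info("simulate: %s clean + %s artifact images, side %s",
                 sim["n_clean"], sim["n_artifact"], spec.side)
        sim_seed = child_seeds(substream(config.seed, "simulate"), 1)[0]
        manifest = generate_dataset(sim["n_clean"], sim["n_artifact"], spec,
                                    seed=sim_seed, out_dir=data_dir,
                                    artifact_kinds=tuple(sim.get("kinds", ARTIFACT_KINDS)))
        manifest["abspath"] = [str(data_dir / p) for p in manifest["path"]]
    elif not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)

    clean_rows = manifest[manifest["label"] == "clean"]
    if clean_rows.empty:
        raise ValidationError("pipeline needs clean-labeled images for training")
    n_train = config.n_train_clean if config.n_train_clean is not None else len(clean_rows) // 2
    if n_train < 1 or n_train > len(clean_rows):
        raise ValidationError(
            f"n_train_clean={n_train} invalid for {len(clean_rows)} clean images"
        )
    train_rows = clean_rows.iloc[:n_train]
    score_rows = manifest[~manifest["path"].isin(train_rows["path"])]
    overlap = set(train_rows["path"]) & set(score_rows["path"])
    if overlap:
        raise ValidationError(f"images in both training and scoring roles: {sorted(overlap)}")
    if score_rows.empty:
        raise ValidationError("no images left to score after the training split")

    log.info("preprocess: %d training / %d scoring images", len(train_rows), len(score_rows))
    x_train = _load_preprocessed(train_rows["abspath"], config)
    x_score = _load_preprocessed(score_rows["abspath"], config)

    cae_cfg = config.cae.replace(seed=child_seeds(substream(config.seed, "train"), 1)[0])
    model = build_cae(cae_cfg)
    log.info("train: %d images, %d epochs, side %d, filters %s",
             len(x_train), cae_cfg.epochs, cae_cfg.effective_side, cae_cfg.effective_filters)
    truth = score_rows["label"].to_numpy()
    has_truth = set(np.unique(truth)) == {"clean", "artifact"}
    if has_truth:
        model.train(x_train, clean_val=x_score[truth == "clean"],
                    artifact_val=x_score[truth == "artifact"])
    else:
        model.train(x_train)
    model.save(out_dir / "model.npz")
    pd.DataFrame([r.__dict__ for r in model.history]).to_csv(
        out_dir / "history.csv", index=False)

    log.info("score: computing IRE for %d images", len(x_score))
    scores = score_images(model, x_score, image_ids=list(score_rows["path"]),
                          percentile=config.ire_percentile)
    scores.to_csv(out_dir / "ires.csv", index=False)

    if config.fixed_threshold is not None:
        thr_value = config.fixed_threshold
        thr = None
    else:
        thr = dataset_threshold(scores["ire"], multiplier=config.threshold_multiplier)
        thr_value = thr.threshold
    with open(out_dir / "threshold.json", "w") as fh:
        json.dump({"threshold": thr_value,
                   "q25": None if thr is None else thr.q25,
                   "q50": None if thr is None else thr.q50}, fh, indent=2)

    labels = classify(scores["ire"], thr_value)
    pd.DataFrame({"path": scores["image_id"], "predicted": labels}).to_csv(
        out_dir / "labels.csv", index=False)

    report = None
    if has_truth:
        boot_seed = child_seeds(substream(config.seed, "bootstrap"), 1)[0]
        report = evaluate_dataset(truth, scores["ire"].to_numpy(), threshold=thr_value,
                                  n_subsets=config.n_subsets, seed=boot_seed)
        report.to_json(out_dir / "report.json")
        log.info("evaluate: accuracy %.1f%%, mean AUC %.4f, p=%.3g",
                 report.accuracy, report.mean_auc, report.p_value)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return {"manifest": manifest, "train_paths": list(train_rows["path"]),
            "scores": scores, "threshold": thr_value, "predicted": labels,
            "report": report, "model": model}


def desk_scale_experiment(master_seed: int, n_train: int = 200,
                          n_eval_clean: int = 50, n_eval_artifact: int = 50,
                          raw_side: int = 256, filters: tuple[int, int] = (16, 32),
                          epochs: int = 8, n_subsets: int = 1000,
                          verbose: bool = False) -> dict:
    """Seeded in-memory synthetic study at desk scale.

    Simulates ``n_train`` clean raw images plus a held-out evaluation set
    (clean and artifact-laden, the four artifact kinds cycled), preprocesses
    them to ``raw_side / 2`` inputs, trains the scaled autoencoder on the
    clean training images, scores the held-out set, applies the adaptive
    threshold, and evaluates. Emitter count scales with image area relative
    to the 1000x1000 default so signal density matches the full-scale scene.
    """
    n_signals = max(1, round(300 * (raw_side / 1000) ** 2))
    template = SceneSpec(side=raw_side, n_signals=n_signals)

    sim_seq = substream(master_seed, "simulate")
    seeds = child_seeds(sim_seq, n_train + n_eval_clean + n_eval_artifact)
    images, labels = [], []
    for i in range(n_train + n_eval_clean):
        images.append(generate_image(template.replace(seed=seeds[i])))
        labels.append("clean")
    for j in range(n_eval_artifact):
        kind = ARTIFACT_KINDS[j % len(ARTIFACT_KINDS)]
        spec = template.replace(seed=seeds[n_train + n_eval_clean + j],
                                artifact=default_artifact(kind, raw_side))
        images.append(generate_image(spec))
        labels.append("artifact")

    pre = np.asarray([preprocess(im.image) for im in images], dtype=np.float32)
    x_train = pre[:n_train]
    x_eval_clean = pre[n_train:n_train + n_eval_clean]
    x_eval_artifact = pre[n_train + n_eval_clean:]

    train_seed = child_seeds(substream(master_seed, "train"), 1)[0]
    cfg = CAEConfig(input_side=raw_side // 2, filters=filters, epochs=epochs,
                    seed=train_seed)
    model = build_cae(cfg)
    model.train(x_train, clean_val=x_eval_clean, artifact_val=x_eval_artifact,
                verbose=verbose)

    x_eval = np.concatenate([x_eval_clean, x_eval_artifact])
    truth = np.asarray(["clean"] * n_eval_clean + ["artifact"] * n_eval_artifact)
    scores = score_images(model, x_eval)
    ires = scores["ire"].to_numpy()
    clean_ires = ires[truth == "clean"]
    artifact_ires = ires[truth == "artifact"]

    boot_seed = child_seeds(substream(master_seed, "bootstrap"), 1)[0]
    p_value = ttest_ire(clean_ires, artifact_ires)
    mean_auc = bootstrap_auc(clean_ires, artifact_ires, n_subsets=n_subsets,
                             seed=boot_seed)

    # The adaptive threshold presupposes an artifact load below 50%, so the
    # classification metrics are measured on a realistically mixed subset
    # (~25% laden, like typical screened datasets) of the same scored images.
    n_art_cls = max(4, round(n_eval_clean / 3))
    cls_ires = np.concatenate([clean_ires, artifact_ires[:n_art_cls]])
    cls_truth = np.asarray(["clean"] * len(clean_ires) + ["artifact"] * n_art_cls)
    thr = dataset_threshold(cls_ires)
    pred = classify(cls_ires, thr.threshold)
    sens, spec, acc = confusion_metrics(pred, cls_truth)

    return {"model": model, "ires": ires, "truth": truth,
            "p_value": p_value, "mean_auc": mean_auc,
            "threshold": thr, "sensitivity": sens, "specificity": spec,
            "accuracy": acc, "classification_n": (len(clean_ires), n_art_cls),
            "mean_ire_clean": float(clean_ires.mean()),
            "mean_ire_artifact": float(artifact_ires.mean())}
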