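"""Run-directory orchestration: configuration, seeding, provenance and
the stage chain simulate -> train-seg -> (train-gan/transfer) -> segment
-> evaluate -> podometrics -> classify.

Every stage writes its outputs plus a JSON provenance record (config
hash, seed, input hashes) into the run directory; a stage whose outputs
already exist is skipped on re-run, so the chain is resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (MANIFEST_COLUMNS, load_sample, read_manifest,
                      write_image, write_mask)
from .stereology import (StereologyParams, glomerulus_podometrics,
                         records_to_frame)
from .synthetic import CohortSpec, SceneParams, simulate_cohort
from .unet import (LossConfig, TrainConfig, UNetSpec, load_checkpoint,
                   postprocess, predict, save_checkpoint, split_by_subject,
                   train_segmenter)

log = logging.getLogger("podoseg")

__all__ = ["stage_provenance", "write_provenance", "config_hash",
           "simulate_to_dir", "run_pipeline", "load_cohort_spec"]


def config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def stage_provenance(stage: str, config, seed, inputs=()) -> dict:
    return dict(stage=stage, version=__version__,
                config_hash=config_hash(config), seed=int(seed),
                inputs={os.path.basename(str(p)): _file_hash(p)
                        for p in inputs},
                timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))


def write_provenance(outdir, record: dict) -> None:
    path = os.path.join(outdir, f"provenance_{record['stage']}.json")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scene = SceneParams(**raw.pop("scene", {}))
    for key in ("glomeruli_per_subject",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortSpec(scene=scene, **raw)


def simulate_to_dir(spec: CohortSpec, outdir, images: bool = True):
    """Write a synthetic cohort as PNG images/masks plus manifest and
    truth CSVs; byte-identical for identical (spec, seed)."""
    os.makedirs(os.path.join(outdir, "images"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "masks"), exist_ok=True)
    samples, truth = simulate_cohort(spec, images=images)
    rows = []
    for s in samples:
        gid = s.glomerulus_id
        img_path = os.path.join("images", f"{gid}.png")
        gm_path = os.path.join("masks", f"{gid}_glom.png")
        pm_path = os.path.join("masks", f"{gid}_podo.png")
        if images:
            write_image(s.image, os.path.join(outdir, img_path))
        write_mask(s.masks.glom, os.path.join(outdir, gm_path))
        write_mask(s.masks.podo, os.path.join(outdir, pm_path))
        rows.append(dict(subject_id=s.subject_id, glomerulus_id=gid,
                         group=s.group, lesion=s.lesion,
                         image_path=img_path, glom_mask_path=gm_path,
                         podo_mask_path=pm_path,
                         pixel_size_um=spec.pixel_size_um))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    write_provenance(outdir, stage_provenance("simulate", spec, spec.seed))
    return manifest, truth


@dataclass
class RunConfig:
    """End-to-end configuration for `run_pipeline`."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    unet: UNetSpec = field(default_factory=UNetSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    stereology: StereologyParams = field(default_factory=StereologyParams)
    thresholds: tuple = (0.5, 0.5)
    seed: int = 0


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Synthetic end-to-end run: simulate, train, segment, score,
    podometrics, classify. Returns a dict of artifact paths."""
    from .evaluation import dice_pixel
    from .signature import loo_classify, signature_frame

    os.makedirs(outdir, exist_ok=True)
    art = {}

    data_dir = os.path.join(outdir, "data")
    manifest_path = os.path.join(data_dir, "manifest.csv")
    if not os.path.exists(manifest_path):
        os.makedirs(data_dir, exist_ok=True)
        simulate_to_dir(config.cohort, data_dir)
    manifest = read_manifest(manifest_path)
    truth = pd.read_csv(os.path.join(data_dir, "truth.csv"))
    samples = [load_sample(row, root=data_dir)
               for _, row in manifest.iterrows()]
    art["manifest"] = manifest_path

    ckpt = os.path.join(outdir, "segmenter")
    train_set, val_set, test_set = split_by_subject(
        samples, config.train.split_fractions, seed=config.seed)
    if not os.path.exists(ckpt + ".npz"):
        model, history = train_segmenter(train_set, val_set, config.unet,
                                         config.loss, config.train)
        history.to_csv(os.path.join(outdir, "history.csv"), index=False)
        save_checkpoint(model, ckpt, dict(seed=config.train.seed))
        write_provenance(outdir, stage_provenance(
            "train-seg", config.train, config.train.seed, [manifest_path]))
    model = load_checkpoint(ckpt)
    art["checkpoint"] = ckpt + ".npz"

    masks_dir = os.path.join(outdir, "pred_masks")
    os.makedirs(masks_dir, exist_ok=True)
    records, scores = [], []
    for s in samples:
        probs = predict(model, s.image)
        masks, podo_objs = postprocess(probs, s.image.pixel_size_um,
                                       config.thresholds)
        write_mask(masks.glom, os.path.join(masks_dir,
                                            f"{s.glomerulus_id}_glom.png"))
        write_mask(masks.podo, os.path.join(masks_dir,
                                            f"{s.glomerulus_id}_podo.png"))
        scores.append(dict(glomerulus_id=s.glomerulus_id,
                           dice_glom=dice_pixel(s.masks.glom, masks.glom),
                           dice_podo=dice_pixel(s.masks.podo, masks.podo)))
        if masks.glom.sum():
            records.append(glomerulus_podometrics(
                masks, config.stereology, s.subject_id, s.glomerulus_id,
                s.lesion, podo_objects=podo_objs))
    pd.DataFrame(scores).to_csv(os.path.join(outdir, "dice.csv"), index=False)
    glom_csv = os.path.join(outdir, "glom.csv")
    records_to_frame(records).to_csv(glom_csv, index=False)
    art["podometrics"] = glom_csv

    meta = truth[["subject_id", "group"]].drop_duplicates()
    sigs = signature_frame(pd.read_csv(glom_csv), meta)
    sig_csv = os.path.join(outdir, "signatures.csv")
    sigs.to_csv(sig_csv, index=False)
    res = loo_classify(sigs, seed=config.seed)
    with open(os.path.join(outdir, "classification.json"), "w") as fh:
        json.dump(dict(auc_roc=res.auc_roc, auc_pr=res.auc_pr,
                       accuracy=res.accuracy, confusion=res.confusion,
                       oof_prob={s: float(p) for s, p in
                                 zip(res.subject_ids, res.oof_prob)}),
                  fh, indent=2)
    art["classification"] = os.path.join(outdir, "classification.json")
    write_provenance(outdir, stage_provenance("pipeline", config,
                                              config.seed, [glom_csv]))
    return art
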