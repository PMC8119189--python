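"""Desk-scale benchmark experiments used by the test suite and the
acceptance script.

Each function builds its own seeded synthetic inputs, runs the relevant
part of the pipeline from scratch and returns the measured quantities.
Problem sizes are chosen to run on a single CPU core: 120-image cohorts,
128 px (or 64 px) frames, a depth-2/8-filter U-Net and a reduced cycleGAN.
The scaled conditions are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .evaluation import dice_pixel
from .gan import GanSpec, GanTrainConfig, train_cyclegan, transfer
from .imaging import MultiChannelImage
from .signature import loo_classify, signature_frame
from .stereology import (StereologyParams, glomerulus_podometrics,
                         records_to_frame)
from .synthetic import (CohortSpec, DomainShift, SceneParams,
                        apply_domain_shift, render_section, sample_scene,
                        simulate_cohort)
from .unet import (LossConfig, TrainConfig, UNetSpec, predict,
                   split_by_subject, train_segmenter)

__all__ = [
    "seg_cohort_spec", "run_mini_segmentation", "dual_vs_single_comparison",
    "stereology_recovery", "gan_bias_experiment", "signature_classification",
    "signature_null_aucs",
]


# ----------------------------------------------------------------------
# cohort/study conditions
# ----------------------------------------------------------------------
def seg_cohort_spec(seed: int, image_size: int = 128) -> CohortSpec:
    """120-image two-group segmentation cohort (10+10 subjects x 6
    glomeruli). Glomerular geometry scales with the frame so one
    glomerulus fills most of the field."""
    scale = image_size / 128.0
    scene = SceneParams(glom_radius_mean_um=45.0 * scale,
                        glom_radius_sd_um=4.0 * scale**2,
                        podocyte_count_mean=55.0 * scale**2,
                        podocyte_count_sd=10.0 * scale**2,
                        other_nuclei_ratio=1.5 if scale >= 1.0 else 1.0,
                        nuclear_radius_mean_um=3.5,
                        nuclear_radius_sd_um=0.25)
    return CohortSpec(n_subjects_per_group=10, glomeruli_per_subject=(6, 6),
                      scene=scene, image_size=image_size, pixel_size_um=1.0,
                      seed=seed)


def _mini_train_config(seed: int, epochs: int = 60) -> TrainConfig:
    # desk-scale schedule: few epochs need a larger RMSprop step than the
    # full-scale 1e-5/2000-epoch reference configuration
    return TrainConfig(epochs=epochs, batch_size=4, learning_rate=1e-3,
                       seed=seed)


MINI_UNET = UNetSpec(depth=2, base_filters=8)


def run_mini_segmentation(seed: int, image_size: int = 128,
                          epochs: int = 60, heads=("glom", "podo")):
    """Train a mini U-Net on a fresh 120-image cohort; report held-out
    test Dice per task plus the training history."""
    samples, truth = simulate_cohort(seg_cohort_spec(seed, image_size))
    train, val, test = split_by_subject(samples, (0.6, 0.2, 0.2), seed=seed)
    model, history = train_segmenter(train, val, MINI_UNET, LossConfig(),
                                     _mini_train_config(seed, epochs),
                                     heads=heads)
    dice = {name: [] for name in heads}
    for s in test:
        probs = predict(model, s.image)
        prob_of = dict(glom=probs.glom_prob, podo=probs.podo_prob)
        for name in heads:
            dice[name].append(dice_pixel(getattr(s.masks, name),
                                         prob_of[name] >= 0.5))
    out = {f"test_dice_{name}": float(np.mean(v)) for name, v in dice.items()}
    out["history"] = history
    out["model"] = model
    out["test"] = test
    out["samples"] = samples
    out["truth"] = truth
    out["n_images"] = len(samples)
    return out


def dual_vs_single_comparison(seed: int, image_size: int = 64,
                              epochs: int = 60):
    """Dual-head network vs two single-head networks under an identical
    training budget on the same cohort; returns mean test Dice of each
    route and their gap."""
    dual = run_mini_segmentation(seed, image_size, epochs,
                                 heads=("glom", "podo"))
    single_g = run_mini_segmentation(seed, image_size, epochs,
                                     heads=("glom",))
    single_p = run_mini_segmentation(seed, image_size, epochs,
                                     heads=("podo",))
    dual_mean = 0.5 * (dual["test_dice_glom"] + dual["test_dice_podo"])
    single_mean = 0.5 * (single_g["test_dice_glom"]
                         + single_p["test_dice_podo"])
    return dict(dual_mean=dual_mean, single_mean=single_mean,
                gap=abs(dual_mean - single_mean),
                dual=dual, single_glom=single_g, single_podo=single_p)


# ----------------------------------------------------------------------
def stereology_recovery(seed: int, n_glomeruli: int = 200):
    """Estimate podocyte numbers from truth masks of n synthetic
    glomeruli spanning the healthy-to-depleted range; compare with the
    known 3-D counts."""
    params = SceneParams(podocyte_count_dist="uniform",
                         podocyte_count_mean=550.0,
                         podocyte_count_sd=230.0)
    sp = StereologyParams.for_equatorial_sections(section_thickness_um=1.0,
                                                  pixel_size_um=1.0)
    est, true = [], []
    for i in range(n_glomeruli):
        scene = sample_scene(params, (seed, i), with_other_nuclei=False)
        sample = render_section(scene, 1.0, 256, render_image=False,
                                seed=(seed, i, 1))
        rec = glomerulus_podometrics(sample.masks, sp)
        est.append(rec.podocyte_number_est)
        true.append(scene.n_podocytes)
    est = np.asarray(est)
    true = np.asarray(true, dtype=float)
    rel_err = np.abs(est - true) / true
    return dict(mean_rel_err=float(rel_err.mean()),
                spearman=float(spearmanr(est, true).statistic),
                bias=float((est / true).mean()), n=n_glomeruli)


# ----------------------------------------------------------------------
# microscope/operator shift used across the bias experiments: strong
# per-channel gains and background offsets (a second microscope whose
# channel balance dims the podocyte markers), enough to break a segmenter
# trained on the reference domain
BIAS_SHIFT = DomainShift(gain=(1.4, 0.5, 0.22),
                         offset=(0.18, 0.05, 0.01),
                         blur_sigma_px=0.0, noise_sd=0.0)


def _gan_domains(seed: int, image_size: int = 64, n_per_domain: int = 48):
    """Two unpaired sets of healthy glomeruli from the same distribution;
    domain B additionally carries the fixed appearance shift."""
    scale = image_size / 128.0
    scene = SceneParams(glom_radius_mean_um=45.0 * scale,
                        glom_radius_sd_um=1.5,
                        podocyte_count_mean=55.0 * scale**2,
                        podocyte_count_sd=3.0,
                        other_nuclei_ratio=1.0)
    n_subjects = max(-(-2 * n_per_domain // 4), 4)   # 4 glomeruli/subject
    spec = CohortSpec(n_subjects_per_group=n_subjects,
                      glomeruli_per_subject=(4, 4), scene=scene,
                      lesion_fraction=0.0,
                      image_size=image_size, pixel_size_um=1.0, seed=seed)
    samples, _ = simulate_cohort(spec)
    controls = [s for s in samples if s.group == "control"]
    if len(controls) < 2 * n_per_domain:
        raise ValueError("cohort too small for the requested domains")
    a_samples = controls[:n_per_domain]
    b_source = controls[n_per_domain:2 * n_per_domain]
    b_samples = []
    for k, s in enumerate(b_source):
        shifted = apply_domain_shift(s.image, BIAS_SHIFT, seed=(seed, 7, k))
        b_samples.append(replace(s, image=shifted))
    return a_samples, b_samples


def gan_bias_experiment(seed: int, epochs: int = 10, image_size: int = 64,
                        seg_epochs: int = 30):
    """CycleGAN bias-minimization rehearsal on two synthetic domains.

    Measures (i) the generator-loss trend over training, (ii) how much
    transfer shrinks the channel-mean gap between the shifted domain and
    the reference, and (iii) whether a segmenter trained on the reference
    domain scores higher podocyte Dice on transferred images than on raw
    shifted images.
    """
    a_samples, b_samples = _gan_domains(seed, image_size)
    n_train = len(a_samples) - 8
    a_imgs = [s.image.pixels for s in a_samples]
    b_imgs = [s.image.pixels for s in b_samples]
    g_ab, g_ba, history = train_cyclegan(
        a_imgs[:n_train], b_imgs[:n_train], GanSpec.mini(),
        GanTrainConfig(epochs=epochs, seed=seed,
                       lr_constant_epochs=max(epochs // 2, 1)),
        a_val=a_imgs[n_train:], b_val=b_imgs[n_train:])

    # channel-mean gap, shifted domain vs reference, before/after transfer
    mean_a = np.mean([im.mean(axis=(0, 1)) for im in a_imgs], axis=0)
    mean_b = np.mean([im.mean(axis=(0, 1)) for im in b_imgs], axis=0)
    transferred = [transfer(im, g_ba, pyramid_levels=0) for im in b_imgs]
    mean_t = np.mean([im.mean(axis=(0, 1)) for im in transferred], axis=0)
    gap_before = float(np.abs(mean_b - mean_a).mean())
    gap_after = float(np.abs(mean_t - mean_a).mean())

    # segmentation transfer: train on the reference domain only
    seg_train = a_samples[:n_train]
    seg_val = a_samples[n_train:]
    model, _ = train_segmenter(seg_train, seg_val, MINI_UNET, LossConfig(),
                               _mini_train_config(seed, seg_epochs))

    def podo_dice(images):
        scores = []
        for s, im in zip(b_samples, images):
            probs = predict(model, MultiChannelImage(
                im, s.image.channel_roles, s.image.pixel_size_um))
            scores.append(dice_pixel(s.masks.podo, probs.podo_prob >= 0.5))
        return float(np.mean(scores))

    dice_raw = podo_dice(b_imgs)
    dice_transferred = podo_dice(transferred)
    return dict(loss_first=float(history["total"].iloc[0]),
                loss_last=float(history["total"].iloc[-1]),
                gap_before=gap_before, gap_after=gap_after,
                gap_reduction=1.0 - gap_after / gap_before,
                dice_raw=dice_raw, dice_transferred=dice_transferred,
                best_epoch=int(history.attrs["best_epoch"]),
                history=history)


# ----------------------------------------------------------------------
def _signature_cohort_spec(seed: int, effect: bool) -> CohortSpec:
    scene = SceneParams(glom_radius_mean_um=45.0, glom_radius_sd_um=4.0,
                        podocyte_count_mean=55.0, podocyte_count_sd=10.0)
    if effect:
        return CohortSpec(n_subjects_per_group=20,
                          glomeruli_per_subject=(5, 7), scene=scene,
                          disease_count_multiplier=0.6,
                          disease_nuclear_radius_multiplier=np.sqrt(1.3),
                          lesion_fraction=0.3, image_size=128,
                          pixel_size_um=1.0, seed=seed)
    return CohortSpec(n_subjects_per_group=20, glomeruli_per_subject=(5, 7),
                      scene=scene, disease_count_multiplier=1.0,
                      disease_nuclear_radius_multiplier=1.0,
                      disease_glom_radius_multiplier=1.0,
                      lesion_fraction=0.0, image_size=128,
                      pixel_size_um=1.0, seed=seed)


def signature_classification(seed: int, effect: bool = True,
                             feature_subset="signature_25"):
    """Truth-mask podometrics -> subject signatures -> LOO logistic
    classification on a 20+20 cohort; returns the pooled AUC."""
    spec = _signature_cohort_spec(seed, effect)
    samples, truth = simulate_cohort(spec, images=False)
    sp = StereologyParams.for_equatorial_sections(pixel_size_um=spec.pixel_size_um)
    records = [glomerulus_podometrics(s.masks, sp, s.subject_id,
                                      s.glomerulus_id, s.lesion)
               for s in samples]
    glom = records_to_frame(records)
    meta = truth[["subject_id", "group"]].drop_duplicates()
    sigs = signature_frame(glom, meta)
    res = loo_classify(sigs, feature_subset=feature_subset, seed=seed)
    return dict(auc=res.auc_roc, auc_pr=res.auc_pr, accuracy=res.accuracy,
                result=res, signatures=sigs, glom=glom)


def signature_null_aucs(seed: int, n_seeds: int = 10):
    """LOO AUC on cohorts with no group effect, across independent seeds."""
    aucs = []
    for k in range(n_seeds):
        sub_seed = int(np.random.SeedSequence((seed, k)).generate_state(1)[0]
                       % (2**31))
        aucs.append(signature_classification(sub_seed, effect=False)["auc"])
    return aucs
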