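"""Dual-output segmentation U-Net for glomeruli and podocyte nuclei.

A single encoder/decoder with two sigmoid heads segments the glomerular
area and the podocyte nuclear area simultaneously from a 3-channel
fluorescence image. Training uses a balanced two-task binary
cross-entropy in which the currently poorer performing task receives the
larger weight, border-emphasizing weight maps on the podocyte task to
keep narrowly spaced nuclei separated, on-the-fly geometric augmentation,
and subject-grouped data splits. Model selection keeps the weights with
the best validation Dice (mean of both tasks).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import nn
from .evaluation import dice_pixel
from .imaging import (LabeledObjects, MaskPair, MultiChannelImage, SegSample,
                      filter_small_objects, label_objects)
from .nn import Tensor

__all__ = [
    "UNetSpec", "LossConfig", "TrainConfig", "ProbabilityPair", "WeightMap",
    "DualUNet", "build_dual_unet", "bce", "balanced_dual_loss",
    "class_balance_map", "compute_weight_map", "augment", "split_by_subject",
    "train_segmenter", "predict", "postprocess",
    "save_checkpoint", "load_checkpoint",
]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class UNetSpec:
    """Architecture: `depth` encoder levels with `base_filters` doubling
    per level down to a bottom layer of base_filters * 2**depth."""

    depth: int = 3
    base_filters: int = 32
    batch_norm: bool = True
    skip_connections: bool = True
    dropout_bottom: bool = True
    dropout_rate: float = 0.5

    @property
    def bottom_filters(self) -> int:
        return self.base_filters * 2**self.depth

    @property
    def filter_schedule(self) -> tuple:
        down = [self.base_filters * 2**d for d in range(self.depth)]
        return tuple(down) + (self.bottom_filters,) + tuple(reversed(down))


@dataclass
class LossConfig:
    epsilon: float = 1e-7
    w0: float = 10.0          # border-term amplitude in the weight map
    sigma_px: float = 5.0     # Gaussian width of the border term
    use_weight_maps: bool = True
    class_floor: float = 0.01  # lower bound on class frequency for weights

    def __post_init__(self):
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.w0 < 0 or self.sigma_px <= 0:
            raise ValueError("w0 must be >= 0 and sigma_px > 0")


@dataclass
class TrainConfig:
    epochs: int = 2000
    batch_size: int = 2
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-5
    flips: bool = True
    shifts: bool = True
    max_shift_frac: float = 0.1
    rotations: bool = True
    max_rotation_deg: float = 45.0
    seed: int = 0
    split_fractions: tuple = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class ProbabilityPair:
    glom_prob: np.ndarray
    podo_prob: np.ndarray

    def __post_init__(self):
        for p in (self.glom_prob, self.podo_prob):
            if p.min() < 0 or p.max() > 1:
                raise ValueError("probabilities outside [0, 1]")
        if self.glom_prob.shape != self.podo_prob.shape:
            raise ValueError("probability maps differ in shape")


@dataclass
class WeightMap:
    w: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.w).all():
            raise ValueError("weight map must be finite")


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------
def _conv_block(cin, cout, rng, batch_norm):
    mods = [nn.Conv2d(cin, cout, 3, rng, bias=not batch_norm)]
    if batch_norm:
        mods.append(nn.BatchNorm2d(cout))
    mods.append(nn.ReLU())
    return nn.Sequential(*mods)


class DualUNet(nn.Module):
    """U-Net with a configurable number of sigmoid output heads."""

    def __init__(self, spec: UNetSpec, seed=0, heads=("glom", "podo")):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xD0)))
        self.spec = spec
        self.head_names = tuple(heads)
        self.enc = []
        cin = 3
        for d in range(spec.depth):
            fo = spec.base_filters * 2**d
            self.enc.append(nn.Sequential(
                _conv_block(cin, fo, rng, spec.batch_norm),
                _conv_block(fo, fo, rng, spec.batch_norm)))
            cin = fo
        fb = spec.bottom_filters
        self.bottom = nn.Sequential(_conv_block(cin, fb, rng, spec.batch_norm),
                                    _conv_block(fb, fb, rng, spec.batch_norm))
        self.drop = nn.Dropout(
            spec.dropout_rate if spec.dropout_bottom else 0.0,
            np.random.default_rng(np.random.SeedSequence((int(seed), 0xDD))))
        self.ups, self.dec = [], []
        cin = fb
        for d in reversed(range(spec.depth)):
            fo = spec.base_filters * 2**d
            self.ups.append(nn.ConvTranspose2d(cin, fo, 2, rng, stride=2))
            dec_in = 2 * fo if spec.skip_connections else fo
            self.dec.append(nn.Sequential(
                _conv_block(dec_in, fo, rng, spec.batch_norm),
                _conv_block(fo, fo, rng, spec.batch_norm)))
            cin = fo
        self.heads = [nn.Conv2d(cin, 1, 1, rng) for _ in self.head_names]

    def forward(self, x) -> dict:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        H, W = x.shape[1:3]
        m = 2**self.spec.depth
        if H % m or W % m:
            raise ValueError(f"spatial size must be divisible by {m}; "
                             "use predict() for automatic reflect padding")
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        x = self.drop(self.bottom(x))
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x)
            if self.spec.skip_connections:
                x = nn.concat([skip, x], axis=3)
            x = dec(x)
        return {name: head(x).sigmoid()
                for name, head in zip(self.head_names, self.heads)}

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_dual_unet(spec: UNetSpec, seed=0, heads=("glom", "podo")) -> DualUNet:
    return DualUNet(spec, seed=seed, heads=heads)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------
def bce(y, yhat, epsilon: float = 1e-7, weights=None):
    """Binary cross-entropy, mean over pixels, with ε-clipped predictions.

    Numpy inputs give a float (float64 math); a Tensor prediction gives a
    differentiable scalar Tensor. `weights` multiplies the per-pixel terms
    before averaging (weight maps are normalized to mean ~1).
    """
    if isinstance(yhat, Tensor):
        return nn.weighted_bce(yhat, y, weights=weights, epsilon=epsilon)
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(yhat, dtype=np.float64), epsilon, 1.0 - epsilon)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    term = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if weights is not None:
        term = np.asarray(weights, dtype=np.float64) * term
    return float(term.mean())


def balance_weights(bce_podo: float, bce_glom: float) -> tuple:
    """Task weights proportional to each task's current BCE (the poorer
    task gets more importance); equal split when both are zero."""
    if bce_podo < 0 or bce_glom < 0:
        raise ValueError("BCE terms must be nonnegative")
    s = bce_podo + bce_glom
    if s == 0:
        return 0.5, 0.5
    return bce_podo / s, bce_glom / s


def balanced_dual_loss(bce_podo: float, bce_glom: float) -> float:
    """L = w_p BCE_podo + w_g BCE_glom with w_p = BCE_podo/(BCE_podo+BCE_glom)."""
    w_p, w_g = balance_weights(bce_podo, bce_glom)
    return w_p * bce_podo + w_g * bce_glom


def class_balance_map(mask: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Per-image class weights inversely proportional to class frequency,
    normalized to mean 1 over the image."""
    mask = np.asarray(mask) > 0
    p = float(np.clip(mask.mean(), floor, 1.0 - floor))
    w_fg, w_bg = 1.0 / (2.0 * p), 1.0 / (2.0 * (1.0 - p))
    return np.where(mask, w_fg, w_bg).astype(np.float32)


def compute_weight_map(mask: np.ndarray, w0: float = 10.0,
                       sigma_px: float = 5.0,
                       class_floor: float = 0.01) -> WeightMap:
    """Border-emphasizing weight map
    w(x) = w_c(x) + w0 exp(-(d1 + d2)^2 / (2 sigma^2)),
    with d1/d2 the distances to the nearest and second-nearest object.
    With fewer than two objects the missing distances are infinite and the
    map reduces to the class map."""
    wc = class_balance_map(mask, class_floor)
    objs = label_objects(mask, 1.0, connectivity=8)
    if w0 == 0 or objs.n_objects < 2:
        return WeightMap(wc)
    dists = np.stack([ndi.distance_transform_edt(objs.labels != k)
                      for k in range(1, objs.n_objects + 1)])
    part = np.partition(dists, 1, axis=0)
    d12 = part[0] + part[1]
    w = wc + w0 * np.exp(-d12**2 / (2.0 * sigma_px**2))
    return WeightMap(w.astype(np.float32))


# ----------------------------------------------------------------------
# augmentation and splitting
# ----------------------------------------------------------------------
def draw_transform(rng, config: TrainConfig, shape) -> tuple:
    fliph = bool(config.flips and rng.random() < 0.5)
    flipv = bool(config.flips and rng.random() < 0.5)
    angle = float(rng.uniform(-config.max_rotation_deg,
                              config.max_rotation_deg)) if config.rotations else 0.0
    dy = dx = 0.0
    if config.shifts:
        dy = float(rng.uniform(-1, 1) * config.max_shift_frac * shape[0])
        dx = float(rng.uniform(-1, 1) * config.max_shift_frac * shape[1])
    return fliph, flipv, angle, dy, dx


def apply_transform(arr: np.ndarray, transform, order: int = 1,
                    mode: str = "constant", cval: float = 0.0) -> np.ndarray:
    """Apply (fliph, flipv, angle_deg, dy, dx) to a 2-D array or an
    H x W x C channels-last array."""
    fliph, flipv, angle, dy, dx = transform
    a = np.asarray(arr, dtype=np.float32)
    if fliph:
        a = a[:, ::-1]
    if flipv:
        a = a[::-1]
    if angle or dy or dx:
        # one fused rotation-about-center + translation (single interpolation)
        th = np.deg2rad(angle)
        rot = np.array([[np.cos(th), -np.sin(th)],
                        [np.sin(th), np.cos(th)]])
        center = (np.array(a.shape[:2]) - 1) / 2.0
        offset = center - rot @ (center + np.array([dy, dx]))
        if a.ndim == 3:
            rot3 = np.eye(3)
            rot3[:2, :2] = rot
            off3 = np.append(offset, 0.0)
            a = ndi.affine_transform(a, rot3, off3, order=order, mode=mode,
                                     cval=cval)
        else:
            a = ndi.affine_transform(a, rot, offset, order=order, mode=mode,
                                     cval=cval)
    return np.ascontiguousarray(a)


def augment(sample: SegSample, config: TrainConfig, seed=0,
            transform=None) -> SegSample:
    """Apply one random (or given) geometric transform identically to the
    image and both masks; masks are re-binarized at 0.5 after bilinear
    interpolation."""
    rng = np.random.default_rng(seed)
    t = transform if transform is not None else draw_transform(
        rng, config, sample.image.shape)
    img = np.clip(apply_transform(sample.image.pixels, t, order=1), 0.0, 1.0)
    glom = apply_transform(sample.masks.glom.astype(np.float32), t) > 0.5
    podo = apply_transform(sample.masks.podo.astype(np.float32), t) > 0.5
    image = MultiChannelImage(img, sample.image.channel_roles,
                              sample.image.pixel_size_um,
                              sample.image.source_id)
    masks = MaskPair(glom, podo, sample.masks.pixel_size_um)
    return SegSample(image, masks, sample.subject_id, sample.glomerulus_id,
                     sample.group, sample.lesion)


def split_by_subject(samples, fractions=(0.6, 0.2, 0.2), seed=0):
    """Partition samples into train/val/test by whole subjects.

    Subjects are shuffled and assigned greedily so realized image counts
    track the target fractions; no subject ever spans two splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_subject: dict = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s)
    subjects = sorted(by_subject)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for a 3-way split")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_total = len(samples)
    cum_targets = np.cumsum(fractions) * n_total
    subject_splits = [[], [], []]
    cum = 0
    si = 0
    for j, subj in enumerate(subjects):
        remaining = len(subjects) - j
        still_empty = sum(1 for k in range(si + 1, 3)
                          if not subject_splits[k])
        # advance when the image quota is met, or when exactly enough
        # subjects remain to give each later split at least one
        if subject_splits[si] and (cum >= cum_targets[si] - 1e-9
                                   or remaining <= still_empty):
            si = min(si + 1, 2)
        subject_splits[si].append(subj)
        cum += len(by_subject[subj])
    splits = [[s for subj in part for s in by_subject[subj]]
              for part in subject_splits]
    train, val, test = splits
    if not (train and val and test):
        raise ValueError("split produced an empty subset; add subjects")
    return train, val, test


# ----------------------------------------------------------------------
# training and inference
# ----------------------------------------------------------------------
def _sample_arrays(sample: SegSample, loss_config: LossConfig):
    img = sample.image.pixels.astype(np.float32)
    glom = sample.masks.glom.astype(np.float32)
    podo = sample.masks.podo.astype(np.float32)
    glom_w = class_balance_map(glom, loss_config.class_floor)
    if loss_config.use_weight_maps:
        podo_w = compute_weight_map(podo, loss_config.w0,
                                    loss_config.sigma_px,
                                    loss_config.class_floor).w
    else:
        podo_w = class_balance_map(podo, loss_config.class_floor)
    return img, glom, podo, glom_w, podo_w


def _augmented_batch(items, idxs, rng, config: TrainConfig):
    imgs, gloms, podos, gws, pws = [], [], [], [], []
    for i in idxs:
        img, glom, podo, gw, pw = items[i]
        t = draw_transform(rng, config, img.shape[:2])
        imgs.append(np.clip(apply_transform(img, t, order=1), 0.0, 1.0))
        gloms.append((apply_transform(glom, t) > 0.5).astype(np.float32))
        podos.append((apply_transform(podo, t) > 0.5).astype(np.float32))
        gws.append(apply_transform(gw, t, order=1, mode="nearest"))
        pws.append(apply_transform(pw, t, order=1, mode="nearest"))
    to_batch = lambda lst: np.stack(lst)[..., None]   # (N, H, W, 1)
    return (np.stack(imgs), to_batch(gloms), to_batch(podos), to_batch(gws),
            to_batch(pws))


def _val_dice(model: DualUNet, val_samples, chunk: int = 8) -> dict:
    model.eval()
    scores = {name: [] for name in model.head_names}
    for start in range(0, len(val_samples), chunk):
        part = val_samples[start:start + chunk]
        batch = np.stack([s.image.pixels for s in part])
        probs = model.forward(batch)
        for k, s in enumerate(part):
            for name in model.head_names:
                gt = getattr(s.masks, name)
                pred = probs[name].data[k, :, :, 0] >= 0.5
                scores[name].append(dice_pixel(gt, pred))
    model.train()
    return {name: float(np.mean(v)) for name, v in scores.items()}


def train_segmenter(train_samples, val_samples, unet_spec: UNetSpec,
                    loss_config: LossConfig, train_config: TrainConfig,
                    heads=("glom", "podo"), verbose: bool = False):
    """Train a (dual or single head) segmentation U-Net.

    Returns (model, history): the model carries the weights of the epoch
    with the best validation Dice (mean over its heads); history has one
    row per epoch with the train loss and per-task validation Dice.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be nonempty")
    seed = train_config.seed
    model = DualUNet(unet_spec, seed=seed, heads=heads)
    if train_config.optimizer.lower() != "rmsprop":
        raise ValueError("only the RMSprop optimizer is supported")
    opt = nn.RMSprop(model.parameters(), lr=train_config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    aug_rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))

    items = [_sample_arrays(s, loss_config) for s in train_samples]
    n = len(items)
    bs = train_config.batch_size
    rows = []
    best = (-1.0, None)
    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idxs = order[start:start + bs]
            img, glom, podo, gw, pw = _augmented_batch(items, idxs, aug_rng,
                                                       train_config)
            out = model.forward(img)
            terms = {}
            if "glom" in out:
                terms["glom"] = bce(glom, out["glom"], loss_config.epsilon,
                                    weights=gw)
            if "podo" in out:
                terms["podo"] = bce(podo, out["podo"], loss_config.epsilon,
                                    weights=pw)
            if len(terms) == 2:
                w_p, w_g = balance_weights(terms["podo"].item(),
                                           terms["glom"].item())
                loss = terms["podo"] * w_p + terms["glom"] * w_g
            else:
                loss = next(iter(terms.values()))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val = _val_dice(model, val_samples)
        mean_val = float(np.mean(list(val.values())))
        rows.append(dict(epoch=epoch, train_loss=float(np.mean(losses)),
                         val_dice_glom=val.get("glom", np.nan),
                         val_dice_podo=val.get("podo", np.nan),
                         val_dice_mean=mean_val))
        if mean_val > best[0]:
            best = (mean_val, model.state_dict())
        if verbose:
            print(f"epoch {epoch:4d} loss {rows[-1]['train_loss']:.4f} "
                  f"val {mean_val:.4f}")
    model.load_state_dict(best[1])
    model.eval()
    return model, pd.DataFrame(rows)


def predict(model: DualUNet, image) -> ProbabilityPair:
    """Run inference on one image; reflect-pads to a multiple of
    2**depth and crops back. Deterministic in inference mode."""
    pixels = image.pixels if isinstance(image, MultiChannelImage) else \
        np.asarray(image, dtype=np.float32)
    H, W = pixels.shape[:2]
    m = 2**model.spec.depth
    ph, pw_ = (-H) % m, (-W) % m
    arr = pixels[None]
    if ph or pw_:
        arr = np.pad(arr, ((0, 0), (0, ph), (0, pw_), (0, 0)), mode="reflect")
    was_training = model.training
    model.eval()
    out = model.forward(arr)
    if was_training:
        model.train()
    probs = {name: t.data[0, :H, :W, 0] for name, t in out.items()}
    glom = probs.get("glom", np.zeros((H, W), dtype=np.float32))
    podo = probs.get("podo", np.zeros((H, W), dtype=np.float32))
    return ProbabilityPair(glom, podo)


def postprocess(probs: ProbabilityPair, pixel_size_um: float,
                thresholds=(0.5, 0.5),
                glom_min=(800.0, "um2_area"),
                podo_min=(3.0, "um_diameter")):
    """Threshold, label and size-filter both probability maps.

    The glomerulus task keeps only the largest surviving object (one
    glomerulus per frame). Returns (MaskPair, podocyte LabeledObjects).
    """
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
    glom_bin = probs.glom_prob >= thresholds[0]
    podo_bin = probs.podo_prob >= thresholds[1]

    gobjs = label_objects(glom_bin, pixel_size_um, connectivity=4)
    glom_mask = filter_small_objects(gobjs, glom_min[0], glom_min[1])
    gobjs2 = label_objects(glom_mask, pixel_size_um, connectivity=4)
    if gobjs2.n_objects > 1:
        keep = int(np.argmax(gobjs2.areas_um2)) + 1
        glom_mask = (gobjs2.labels == keep).astype(np.uint8)

    pobjs = label_objects(podo_bin, pixel_size_um, connectivity=8)
    podo_mask = filter_small_objects(pobjs, podo_min[0], podo_min[1])
    podo_objs = label_objects(podo_mask, pixel_size_um, connectivity=8)
    return MaskPair(glom_mask, podo_mask, pixel_size_um), podo_objs


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------
def save_checkpoint(model: DualUNet, path, meta: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with the architecture spec."""
    np.savez(path, **model.state_dict())
    side = dict(unet_spec=asdict(model.spec), heads=list(model.head_names))
    side.update(meta or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=2)


def load_checkpoint(path) -> DualUNet:
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    spec = UNetSpec(**side["unet_spec"])
    model = DualUNet(spec, seed=0, heads=tuple(side["heads"]))
    npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    if not os.path.exists(npz_path):
        npz_path = str(path)
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model
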