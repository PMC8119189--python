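"""U-Net cycleGAN for annotation-free bias minimization.

Two generators (A->B and B->A) and two patch discriminators are trained
on unpaired images from a reference domain and a shifted domain
(different microscope/operator). The generator is an encoder /
ResNet-transformer / decoder with skip concatenations from encoder to
decoder; the discriminator is a strided patch classifier. Losses:
least-squares adversarial loss, L1 cycle-consistency (weight lambda_cyc)
and L1 identity loss (weight lambda_id). Model selection keeps the epoch
with the lowest validation loss (cycle + identity on held-out images).

Images enter the networks scaled to [-1, 1]; `transfer` handles the
[0, 1] <-> [-1, 1] rescaling and the pyramid round trip for images larger
than the working size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .pyramids import pyramid_down, pyramid_up

__all__ = [
    "GanSpec", "GanTrainConfig", "Generator", "Discriminator",
    "build_generator", "build_discriminator", "cyclegan_step",
    "train_cyclegan", "transfer", "lr_schedule",
    "save_generator", "load_generator",
]


# ----------------------------------------------------------------------
@dataclass
class GanSpec:
    """Architecture hyperparameters; defaults follow the reference
    configuration (encoder 64/128/256, 9 ResNet blocks, 6-layer patch
    discriminator)."""

    enc_filters: tuple = (64, 128, 256)
    enc_kernels: tuple = (7, 3, 3)
    enc_strides: tuple = (1, 2, 2)
    n_resblocks: int = 9
    dec_filters: tuple = (128, 64, 3)
    dec_kernels: tuple = (3, 3, 7)
    dec_strides: tuple = (2, 2, 1)
    disc_filters: tuple = (64, 128, 256, 512, 512, 1)
    disc_kernel: int = 4
    disc_strides: tuple = (2, 2, 2, 2, 1, 1)
    leaky_slope: float = 0.2
    lambda_cyc: float = 10.0
    lambda_id: float = 5.0

    @classmethod
    def mini(cls):
        """Desk-scale configuration for 64 px smoke experiments."""
        return cls(enc_filters=(8, 16, 32), n_resblocks=2,
                   dec_filters=(16, 8, 3),
                   disc_filters=(8, 16, 32, 32, 32, 1))


@dataclass
class GanTrainConfig:
    epochs: int = 200
    lr: float = 2e-4
    lr_constant_epochs: int = 100
    batch_size: int = 1
    seed: int = 0
    image_buffer: int = 50
    adversarial: str = "lsgan"      # or "bce"


def lr_schedule(epoch: int, config: GanTrainConfig) -> float:
    """Constant lr for the first `lr_constant_epochs`, then linear decay
    reaching 0 at `epochs`."""
    if epoch < config.lr_constant_epochs:
        return config.lr
    span = max(config.epochs - config.lr_constant_epochs, 1)
    frac = (config.epochs - epoch) / span
    return config.lr * max(frac, 0.0)


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------
class _ConvIN(nn.Module):
    def __init__(self, cin, cout, k, rng, stride=1, norm=True, act="relu",
                 slope=0.2, transposed=False, init_std=0.02):
        super().__init__()
        if transposed:
            self.conv = nn.ConvTranspose2d(cin, cout, k, rng, stride=stride,
                                           init_std=init_std)
        else:
            self.conv = nn.Conv2d(cin, cout, k, rng, stride=stride,
                                  init_std=init_std)
        self.norm = nn.InstanceNorm2d(cout) if norm else None
        self.act, self.slope = act, slope

    def forward(self, x):
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        if self.act == "relu":
            return x.relu()
        if self.act == "leaky":
            return x.leaky_relu(self.slope)
        if self.act == "tanh":
            return x.tanh()
        return x


class ResBlock(nn.Module):
    """Two 3x3 convolutions with instance norm; ReLU on the first only;
    additive residual path (all-zero weights give the identity map)."""

    def __init__(self, c, rng):
        super().__init__()
        self.c1 = _ConvIN(c, c, 3, rng, act="relu")
        self.c2 = _ConvIN(c, c, 3, rng, act="none")

    def forward(self, x):
        return x + self.c2(self.c1(x))


class Generator(nn.Module):
    """Encoder / ResNet transformer / decoder with skip concatenations
    from each encoder level into the matching decoder level; tanh output
    in [-1, 1]."""

    def __init__(self, spec: GanSpec, seed=0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x6E)))
        self.spec = spec
        f = spec.enc_filters
        self.enc = []
        cin = 3
        for fo, k, s in zip(f, spec.enc_kernels, spec.enc_strides):
            self.enc.append(_ConvIN(cin, fo, k, rng, stride=s))
            cin = fo
        self.res = [ResBlock(cin, rng) for _ in range(spec.n_resblocks)]
        self.dec = []
        # decoder input at level i = concat(previous output, encoder skip)
        skip_ch = list(reversed(f))          # encoder outputs, deepest first
        for i, (fo, k, s) in enumerate(zip(spec.dec_filters, spec.dec_kernels,
                                           spec.dec_strides)):
            is_last = i == len(spec.dec_filters) - 1
            self.dec.append(_ConvIN(cin + skip_ch[i], fo, k, rng, stride=s,
                                    transposed=True,
                                    norm=not is_last,
                                    act="tanh" if is_last else "relu"))
            cin = fo

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        skips = []
        for layer in self.enc:
            x = layer(x)
            skips.append(x)
        for block in self.res:
            x = block(x)
        for layer, skip in zip(self.dec, reversed(skips)):
            x = layer(nn.concat([x, skip], axis=3))
        return x


class Discriminator(nn.Module):
    """Patch discriminator: strided convolutions to a logit map
    (256 px input -> 16 x 16 patches)."""

    def __init__(self, spec: GanSpec, seed=0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xD1)))
        self.layers = []
        cin = 3
        n = len(spec.disc_filters)
        for i, (fo, s) in enumerate(zip(spec.disc_filters, spec.disc_strides)):
            first, last = i == 0, i == n - 1
            self.layers.append(_ConvIN(
                cin, fo, spec.disc_kernel, rng, stride=s,
                norm=not (first or last),
                act="none" if last else "leaky", slope=spec.leaky_slope))
            cin = fo

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        for layer in self.layers:
            x = layer(x)
        return x


def build_generator(spec: GanSpec, seed=0) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: GanSpec, seed=0) -> Discriminator:
    return Discriminator(spec, seed)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------
def _adv_loss(logits: Tensor, target: float, kind: str = "lsgan") -> Tensor:
    if kind == "lsgan":
        return (logits - target).square().mean()
    # cross-entropy alternative
    p = logits.sigmoid().clip(1e-7, 1 - 1e-7)
    return -(p.log() if target >= 0.5 else (1.0 - p).log()).mean()


def cyclegan_step(real_a, real_b, g_ab: Generator, g_ba: Generator,
                  d_a: Discriminator, d_b: Discriminator,
                  lambda_cyc: float = 10.0, lambda_id: float = 5.0,
                  adversarial: str = "lsgan"):
    """Compute generator loss components on one unpaired image pair.

    Returns (total_loss Tensor, dict of floats with l_adv, l_cyc, l_id,
    and the generated fakes for the discriminator update).
    Images must be scaled to [-1, 1].
    """
    if real_a.shape != real_b.shape:
        raise ValueError("domain images must share shape")
    a = Tensor(real_a) if isinstance(real_a, np.ndarray) else real_a
    bt = Tensor(real_b) if isinstance(real_b, np.ndarray) else real_b
    fake_b = g_ab(a)
    fake_a = g_ba(bt)
    rec_a = g_ba(fake_b)
    rec_b = g_ab(fake_a)
    id_a = g_ba(a)
    id_b = g_ab(bt)

    l_adv = _adv_loss(d_b(fake_b), 1.0, adversarial) + \
        _adv_loss(d_a(fake_a), 1.0, adversarial)
    l_cyc = (rec_a - a).abs().mean() + (rec_b - bt).abs().mean()
    l_id = (id_b - bt).abs().mean() + (id_a - a).abs().mean()
    total = l_adv + l_cyc * lambda_cyc + l_id * lambda_id
    parts = dict(l_adv=l_adv.item(), l_cyc=l_cyc.item(), l_id=l_id.item(),
                 total=total.item())
    return total, parts, fake_b.data.copy(), fake_a.data.copy()


class _ImageBuffer:
    """Pool of past generated images for discriminator updates (the
    standard cycleGAN history trick)."""

    def __init__(self, size: int, rng):
        self.size, self.rng, self.images = size, rng, []

    def query(self, image: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image)
            return image
        if self.rng.random() < 0.5:
            k = int(self.rng.integers(self.size))
            out = self.images[k]
            self.images[k] = image
            return out
        return image


def _val_loss(g_ab, g_ba, a_val, b_val, lambda_cyc, lambda_id) -> float:
    """Checkpoint-selection signal: cycle + identity losses on held-out
    images (no adversarial term, whose scale drifts with the
    discriminator)."""
    tot = 0.0
    n = 0
    for a in a_val:
        at = Tensor(a[None])
        fb = g_ab(at)
        l = lambda_cyc * np.abs(g_ba(fb).data - at.data).mean() + \
            lambda_id * np.abs(g_ba(at).data - at.data).mean()
        tot += float(l)
        n += 1
    for b in b_val:
        bt = Tensor(b[None])
        fa = g_ba(bt)
        l = lambda_cyc * np.abs(g_ab(fa).data - bt.data).mean() + \
            lambda_id * np.abs(g_ab(bt).data - bt.data).mean()
        tot += float(l)
        n += 1
    return tot / max(n, 1)


def train_cyclegan(domain_a, domain_b, spec: GanSpec,
                   config: GanTrainConfig, a_val=None, b_val=None,
                   verbose: bool = False):
    """Train the two generators and discriminators on unpaired [0,1]
    images (lists of H x W x 3 arrays).

    Returns (g_ab, g_ba, history); the generators carry the weights of
    the epoch with the lowest validation loss.
    """
    if not len(domain_a) or not len(domain_b):
        raise ValueError("both domains need at least one image")
    to_pm1 = lambda imgs: [np.asarray(im, np.float32) * 2.0 - 1.0
                           for im in imgs]
    a_imgs, b_imgs = to_pm1(domain_a), to_pm1(domain_b)
    a_val = to_pm1(a_val) if a_val is not None else a_imgs
    b_val = to_pm1(b_val) if b_val is not None else b_imgs

    seed = config.seed
    g_ab = Generator(spec, seed=np.random.SeedSequence((seed, 0)).generate_state(1)[0])
    g_ba = Generator(spec, seed=np.random.SeedSequence((seed, 1)).generate_state(1)[0])
    d_a = Discriminator(spec, seed=np.random.SeedSequence((seed, 2)).generate_state(1)[0])
    d_b = Discriminator(spec, seed=np.random.SeedSequence((seed, 3)).generate_state(1)[0])
    opt_g = nn.Adam(g_ab.parameters() + g_ba.parameters(), lr=config.lr)
    opt_d = nn.Adam(d_a.parameters() + d_b.parameters(), lr=config.lr)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    buf_a = _ImageBuffer(config.image_buffer, rng)
    buf_b = _ImageBuffer(config.image_buffer, rng)

    rows = []
    best = (np.inf, None, None, -1)
    n = max(len(a_imgs), len(b_imgs))
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        opt_g.lr = opt_d.lr = lr
        order_a = rng.permutation(len(a_imgs))
        order_b = rng.permutation(len(b_imgs))
        parts_sum = dict(l_adv=0.0, l_cyc=0.0, l_id=0.0, total=0.0, d=0.0)
        for k in range(n):
            a = a_imgs[order_a[k % len(a_imgs)]][None]
            b = b_imgs[order_b[k % len(b_imgs)]][None]
            total, parts, fake_b, fake_a = cyclegan_step(
                a, b, g_ab, g_ba, d_a, d_b, spec.lambda_cyc, spec.lambda_id,
                config.adversarial)
            opt_g.zero_grad()
            total.backward()
            opt_g.step()
            # discriminator update on real vs buffered fakes
            d_loss = (_adv_loss(d_a(Tensor(a)), 1.0, config.adversarial)
                      + _adv_loss(d_a(Tensor(buf_a.query(fake_a))), 0.0,
                                  config.adversarial)
                      + _adv_loss(d_b(Tensor(b)), 1.0, config.adversarial)
                      + _adv_loss(d_b(Tensor(buf_b.query(fake_b))), 0.0,
                                  config.adversarial)) * 0.5
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            for key, v in parts.items():
                parts_sum[key] += v
            parts_sum["d"] += d_loss.item()
        vl = _val_loss(g_ab, g_ba, a_val, b_val, spec.lambda_cyc,
                       spec.lambda_id)
        row = {k: v / n for k, v in parts_sum.items()}
        row.update(epoch=epoch, lr=lr, val_loss=vl)
        rows.append(row)
        if vl < best[0]:
            best = (vl, g_ab.state_dict(), g_ba.state_dict(), epoch)
        if verbose:
            print(f"epoch {epoch:3d} total {row['total']:.3f} val {vl:.3f}")
    g_ab.load_state_dict(best[1])
    g_ba.load_state_dict(best[2])
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best[3]
    return g_ab, g_ba, history


def save_generator(generator: Generator, path, meta: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar carrying the GanSpec."""
    np.savez(path, **generator.state_dict())
    side = dict(gan_spec=asdict(generator.spec))
    side.update(meta or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(side, fh, indent=2)


def load_generator(path) -> Generator:
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    raw = side["gan_spec"]
    raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    gen = Generator(GanSpec(**raw), seed=0)
    npz = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    with np.load(npz) as data:
        gen.load_state_dict({k: data[k] for k in data.files})
    gen.eval()
    return gen


def transfer(image, generator: Generator, pyramid_levels: int = 0):
    """Transfer one [0,1] image through a generator at the working size.

    The image is rescaled to [-1, 1], reduced `pyramid_levels` times with
    a Gaussian pyramid, translated, upsampled back with the stored
    Laplacian detail layers, rescaled to [0, 1] and clipped.
    """
    pixels = image.pixels if hasattr(image, "pixels") else \
        np.asarray(image, dtype=np.float32)
    x = pixels * 2.0 - 1.0
    pair = pyramid_down(x, pyramid_levels)
    out = generator(pair.low_res[None]).data[0]
    full = pyramid_up(out, pair.detail_layers)
    return np.clip((full + 1.0) / 2.0, 0.0, 1.0).astype(np.float32)
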