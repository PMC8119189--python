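"""Gaussian/Laplacian pyramid resizing for the bias-transfer workflow.

Full-resolution images are reduced to the GAN working size with a
Gaussian pyramid; the band-pass (Laplacian) detail layers are kept so the
transferred low-resolution image can be upsampled back to the original
size with its high-frequency content restored. The reconstruction
low_res -> expand -> + detail is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import pyramid_expand, pyramid_reduce

__all__ = ["PyramidPair", "pyramid_down", "pyramid_up"]


@dataclass
class PyramidPair:
    low_res: np.ndarray            # (H/2^L, W/2^L, C)
    detail_layers: list            # finest-first Laplacian residuals


def _reduce(img):
    return pyramid_reduce(img, downscale=2, channel_axis=-1,
                          preserve_range=True).astype(np.float32)


def _expand(img, shape):
    out = pyramid_expand(img, upscale=2, channel_axis=-1,
                         preserve_range=True).astype(np.float32)
    return out[:shape[0], :shape[1]]


def pyramid_down(image: np.ndarray, levels: int) -> PyramidPair:
    """Reduce `levels` times; keep the Laplacian residual of every level."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3:
        raise ValueError("expected an H x W x C image")
    H, W = img.shape[:2]
    if levels < 0 or (levels and (H % 2**levels or W % 2**levels)):
        raise ValueError(f"size {H}x{W} not divisible by 2^{levels}")
    details = []
    cur = img
    for _ in range(levels):
        low = _reduce(cur)
        details.append(cur - _expand(low, cur.shape))
        cur = low
    return PyramidPair(cur, details)


def pyramid_up(low_res: np.ndarray, detail_layers: list) -> np.ndarray:
    """Expand-and-add chain restoring the stored high-frequency layers."""
    cur = np.asarray(low_res, dtype=np.float32)
    for detail in reversed(detail_layers):
        if detail.shape[0] != 2 * cur.shape[0] or \
                detail.shape[1] != 2 * cur.shape[1]:
            raise ValueError(
                f"detail layer {detail.shape} does not match 2x {cur.shape}")
        cur = _expand(cur, detail.shape) + detail
    return cur
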