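"""High-resolution attention heatmaps.

The trained attention scorer is evaluated densely across the slide: a
224-pixel window slides with a 32-pixel stride (the output grid of the
fully-convolutional equivalent of the tile model), and the raw attention
logit e = w^T tanh(V h) of each window's feature vector is recorded.  At
stride = window the grid coincides with the tessellation, so the dense map
must reproduce the per-tile attention logits exactly — that equivalence is
the module's primary correctness check.

Display normalization is per-slide min–max of the raw logits; an all-equal
map normalizes to the constant 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attn_mil import AttentionMILParams, attention_logits
from .tile_features import EncoderSpec, encoder_function
from .wsi_prep import SlideImage, TILE_PX

__all__ = ["AttentionHeatmap", "dense_attention_map", "overlay", "save_heatmap"]

DEFAULT_STRIDE = 32


@dataclass
class AttentionHeatmap:
    logits: np.ndarray          # h x w raw attention logits per window
    values: np.ndarray          # h x w min-max normalized to [0, 1]
    stride: int
    window: int
    slide_id: str = ""
    normalization: dict = field(default_factory=dict)

    def window_origin(self, i: int, j: int) -> tuple:
        """(row, col) origin in the resampled slide of grid cell (i, j)."""
        return (i * self.stride, j * self.stride)


def _normalize(logits: np.ndarray) -> tuple:
    lo, hi = float(logits.min()), float(logits.max())
    if hi - lo < 1e-12:
        return np.zeros_like(logits), dict(method="minmax", min=lo, max=hi,
                                           degenerate=True)
    return (logits - lo) / (hi - lo), dict(method="minmax", min=lo, max=hi,
                                           degenerate=False)


def dense_attention_map(slide: SlideImage, encoder, params: AttentionMILParams,
                        window: int = TILE_PX,
                        stride: int = DEFAULT_STRIDE) -> AttentionHeatmap:
    """Slide the attention scorer across the slide on a ``stride`` grid.

    ``encoder`` is an :class:`EncoderSpec` or a callable ``tile -> vector``.
    Windows fully inside the slide only (no padding).  Grid dims are
    floor((H - window) / stride) + 1 by the analogous width count.
    """
    h, w = slide.shape
    if h < window or w < window:
        raise ValueError(f"slide {h}x{w} smaller than window {window}")
    encode = encoder_function(encoder) if isinstance(encoder, EncoderSpec) else encoder
    gh = (h - window) // stride + 1
    gw = (w - window) // stride + 1
    logits = np.empty((gh, gw), dtype=np.float64)
    for i in range(gh):
        r = i * stride
        for j in range(gw):
            c = j * stride
            feat = encode(slide.pixels[r:r + window, c:c + window])
            logits[i, j] = float(attention_logits(feat, params)[0])
    values, norm = _normalize(logits)
    return AttentionHeatmap(logits=logits, values=values, stride=stride,
                            window=window, slide_id=slide.slide_id,
                            normalization=norm)


def overlay(slide: SlideImage, heatmap: AttentionHeatmap, colormap: str = "inferno",
            alpha: float = 0.5, interpolation: str = "bilinear") -> np.ndarray:
    """Alpha-blend the colored heatmap over the slide (RGB uint8 output).

    The grid is upsampled to the slide size with the recorded interpolation;
    ``alpha=0`` returns the slide pixels unchanged.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return slide.pixels.copy()
    from matplotlib import colormaps
    from skimage.transform import resize

    order = 0 if interpolation == "nearest" else 1
    full = resize(heatmap.values, slide.shape, order=order, mode="edge",
                  preserve_range=True, anti_aliasing=False)
    colored = colormaps[colormap](full)[..., :3] * 255.0
    blended = (1.0 - alpha) * slide.pixels.astype(float) + alpha * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def save_heatmap(heatmap: AttentionHeatmap, path) -> None:
    """16-bit single-channel PNG of the normalized map + JSON sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, np.round(heatmap.values * 65535).astype(np.uint16))
    sidecar = dict(stride=heatmap.stride, window=heatmap.window,
                   slide_id=heatmap.slide_id, normalization=heatmap.normalization)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
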