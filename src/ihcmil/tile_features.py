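"""Tile featurization behind a pluggable encoder contract.

The published analysis encoded every kept 224 × 224 tile into a 2,048-d
vector with a large pretrained histopathology network; here the encoder is a
registry-resolved pure function ``tile -> vector`` so any extractor with a
fixed output dimension can be plugged in.  Two deterministic CPU-cheap
encoders ship with the package:

* ``stain_stats`` — physically motivated: per-pixel optical densities are
  unmixed into hematoxylin and DAB concentrations (Ruifrok–Johnston color
  deconvolution) and summarized by histograms, moments, positive-pixel
  fractions and a gradient-energy term.  This is the default and is highly
  informative for membranous DAB staining.
* ``conv_small`` — a small frozen random-filter convolutional encoder, for
  tests that want a texture-generic representation.

The MIL stage never backpropagates into the encoder, so feature bags can be
precomputed once per slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wsi_prep import LUMA, TILE_PX, TileGrid

__all__ = [
    "EncoderSpec",
    "FeatureBag",
    "extract_features",
    "stain_stats_encoder",
    "conv_small_encoder",
    "register_encoder",
    "encoder_function",
    "STAIN_MATRIX",
]

# Ruifrok–Johnston stain vectors for hematoxylin and DAB, rows unit-normalized.
_H = np.array([0.650, 0.704, 0.286])
_D = np.array([0.269, 0.568, 0.778])
STAIN_MATRIX = np.stack([_H / np.linalg.norm(_H), _D / np.linalg.norm(_D)])  # 2 x 3

_HIST_BINS = 16
_HIST_RANGE = (0.0, 2.5)        # unmixed concentration range for histograms
_POS_THRESHOLD = 0.15           # concentration above which a pixel counts positive
BASE_FEATURES = 2 * _HIST_BINS + 2 * 3 + 1   # 39 before tiling to output_dim


@dataclass(frozen=True)
class EncoderSpec:
    """Which encoder to run and the output dimensionality it must produce."""

    name: str = "stain_stats"
    output_dim: int = 2048
    deterministic: bool = True
    config: tuple = ()           # frozen key-value pairs, e.g. (("seed", 0),)

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")

    def config_dict(self) -> dict:
        return dict(self.config)


@dataclass
class FeatureBag:
    """Per-slide MIL bag: one feature row per kept tile, in tile-grid order."""

    slide_id: str
    features: np.ndarray        # N x D float32
    coords: np.ndarray          # N x 2 int64 tile origins (row, col)
    encoder: EncoderSpec

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature bag contains NaN or Inf")
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValueError("features and coords row counts differ")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]


def optical_density(tile: np.ndarray) -> np.ndarray:
    """Beer–Lambert OD per channel: -log10((I + 1) / 256); white maps to ~0."""
    return -np.log10((tile.astype(float) + 1.0) / 256.0)


def unmix_hd(tile: np.ndarray) -> np.ndarray:
    """Least-squares hematoxylin/DAB concentrations per pixel (H x W x 2)."""
    od = optical_density(tile).reshape(-1, 3)
    conc = od @ np.linalg.pinv(STAIN_MATRIX)
    return conc.reshape(tile.shape[0], tile.shape[1], 2)


def _tile_or_pad(vec: np.ndarray, output_dim: int) -> np.ndarray:
    reps = int(np.ceil(output_dim / vec.size))
    return np.tile(vec, reps)[:output_dim].astype(np.float32)


def stain_stats_encoder(tile: np.ndarray, output_dim: int = 2048, **_) -> np.ndarray:
    """Stain-deconvolution summary features, tiled to ``output_dim``.

    Layout of the 39 base features (then repeated cyclically):
    [hematoxylin histogram (16), DAB histogram (16),
     hematoxylin mean/sd/positive-fraction, DAB mean/sd/positive-fraction,
     gradient energy].  Swapping the two stains in a tile swaps the two
    histogram blocks and the two stats triplets.
    """
    conc = unmix_hd(tile)
    hema, dab = conc[..., 0].ravel(), conc[..., 1].ravel()
    feats = []
    npx = hema.size
    for ch in (hema, dab):
        hist, _ = np.histogram(np.clip(ch, *_HIST_RANGE), bins=_HIST_BINS,
                               range=_HIST_RANGE)
        feats.append(hist / npx)
    for ch in (hema, dab):
        feats.append([ch.mean(), ch.std(), float(np.mean(ch > _POS_THRESHOLD))])
    gray = (tile.astype(float) @ LUMA) / 255.0
    gy, gx = np.gradient(gray)
    feats.append([float(np.sqrt(gx * gx + gy * gy).mean())])
    base = np.concatenate([np.asarray(f, dtype=float).ravel() for f in feats])
    return _tile_or_pad(base, output_dim)


def conv_small_encoder(tile: np.ndarray, output_dim: int = 2048,
                       seed: int = 0, **_) -> np.ndarray:
    """Frozen random 3x3 convolutional features on a 4x-downsampled tile.

    Filters are drawn once from a seeded generator, so the encoder is a pure
    deterministic function; it is never trained.
    """
    rng = np.random.default_rng(seed)
    filters = rng.normal(0, 1.0, size=(8, 3, 3, 3)) / 3.0
    small = tile[::4, ::4].astype(float) / 255.0
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(small, (3, 3, 3))[..., 0, :, :, :]  # h x w x 3 x 3 x 3
    resp = np.einsum("hwcij,fijc->hwf", np.moveaxis(win, 4, 2), filters)
    resp = np.maximum(resp, 0.0)
    base = np.concatenate([resp.mean(axis=(0, 1)), resp.max(axis=(0, 1))])
    return _tile_or_pad(base, output_dim)


_ENCODERS = {
    "stain_stats": stain_stats_encoder,
    "conv_small": conv_small_encoder,
}


def register_encoder(name: str, fn) -> None:
    """Register a custom encoder callable ``(tile, output_dim, **config) -> vector``."""
    _ENCODERS[name] = fn


def encoder_function(spec: EncoderSpec):
    """Resolve an EncoderSpec to a closed-over ``tile -> vector`` callable."""
    if spec.name not in _ENCODERS:
        raise KeyError(
            f"unknown encoder {spec.name!r}; registered: {sorted(_ENCODERS)}")
    fn = _ENCODERS[spec.name]
    cfg = spec.config_dict()

    def encode(tile_pixels: np.ndarray) -> np.ndarray:
        vec = fn(tile_pixels, output_dim=spec.output_dim, **cfg)
        if vec.shape != (spec.output_dim,):
            raise ValueError(
                f"encoder {spec.name!r} returned shape {vec.shape}, "
                f"expected ({spec.output_dim},)")
        return vec

    return encode


def extract_features(grid: TileGrid, encoder: EncoderSpec) -> FeatureBag:
    """Encode every kept tile of a TileGrid, preserving grid order."""
    if len(grid.tiles) == 0:
        raise ValueError("empty bag: tile grid has no kept tiles")
    encode = encoder_function(encoder)
    rows = np.stack([encode(t.pixels) for t in grid.tiles]).astype(np.float32)
    return FeatureBag(slide_id=grid.slide_id, features=rows,
                      coords=grid.coords, encoder=encoder)


def save_feature_bag(bag: FeatureBag, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=bag.features)
        fh.create_dataset("coords", data=bag.coords)
        fh.attrs["slide_id"] = bag.slide_id
        fh.attrs["encoder_name"] = bag.encoder.name
        fh.attrs["output_dim"] = bag.encoder.output_dim


def load_feature_bag(path) -> FeatureBag:
    import h5py

    with h5py.File(path, "r") as fh:
        features = fh["features"][...]
        coords = fh["coords"][...]
        spec = EncoderSpec(name=str(fh.attrs["encoder_name"]),
                           output_dim=int(fh.attrs["output_dim"]))
        slide_id = str(fh.attrs["slide_id"])
    return FeatureBag(slide_id=slide_id, features=features, coords=coords,
                      encoder=spec)
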