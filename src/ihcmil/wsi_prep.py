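"""Slide preprocessing: ROI cropping, resampling, tessellation and tile QC.

Slides are cropped to pathologist-annotated polygonal ROIs (QuPath-style
GeoJSON), resampled to the working resolution of 256/224 µm/px (so a 224-px
tile spans 256 µm of tissue), cut into non-overlapping 224 × 224 tiles, and
filtered: tiles whose Canny edge fraction falls below 2% are discarded as
blank or blurry.

Coordinate convention throughout: (row, col), 0-based, origin at the top-left
of the resampled slide, half-open tile extents [r, r+224) × [c, c+224).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, shape
from skimage import feature as skfeature
from skimage import transform as sktransform
from skimage.draw import polygon2mask

__all__ = [
    "SlideImage",
    "ROIPolygon",
    "Tile",
    "TileGrid",
    "CannyParams",
    "TARGET_MPP",
    "TILE_PX",
    "EDGE_THRESHOLD",
    "read_rois_geojson",
    "crop_to_rois",
    "resample_to_mpp",
    "tessellate",
    "edge_fraction",
    "qc_filter",
    "save_tile_grid",
    "load_tile_grid",
]

TILE_PX = 224
TILE_EDGE_UM = 256.0
TARGET_MPP = TILE_EDGE_UM / TILE_PX    # ≈ 1.142857 µm/px
EDGE_THRESHOLD = 0.02

LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SlideImage:
    """An RGB slide with its physical pixel size (µm per pixel)."""

    pixels: np.ndarray      # H x W x 3 uint8
    mpp: float
    slide_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide must have at least one pixel")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ROIPolygon:
    """A closed annotation ring in source-slide pixel coordinates (x, y)."""

    vertices: tuple

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("ROI polygon is self-intersecting or otherwise invalid")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class Tile:
    pixels: np.ndarray      # 224 x 224 x 3 uint8
    origin: tuple           # (row, col) in the resampled slide
    slide_id: str

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != (TILE_PX, TILE_PX):
            raise ValueError(f"tiles must be {TILE_PX}x{TILE_PX}")


@dataclass
class TileGrid:
    """QC bookkeeping: kept tiles plus the per-tile edge fractions and discards."""

    slide_id: str
    tiles: list                     # kept Tile objects, grid order
    edge_fractions: np.ndarray      # per kept tile
    discarded_origins: list         # (row, col) of discarded tiles
    discarded_reasons: list         # parallel to discarded_origins
    discarded_edge_fractions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    threshold: float = EDGE_THRESHOLD

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def coords(self) -> np.ndarray:
        return np.array([t.origin for t in self.tiles], dtype=np.int64).reshape(-1, 2)


@dataclass(frozen=True)
class CannyParams:
    """Canny edge-detector settings used by tile QC.

    Grayscale is ITU-R 601 luminance scaled to [0, 1]; thresholds are
    absolute on that scale (not relative to the per-tile gradient maximum,
    which would make the filter contrast-invariant and let faint noise in a
    blank tile count as edges).
    """

    sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2


def read_rois_geojson(path) -> list:
    """Read Polygon/MultiPolygon features from a QuPath-dialect GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    rois = []
    for feat in feats:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if isinstance(geom, Polygon):
            rois.append(ROIPolygon(vertices=tuple(geom.exterior.coords[:-1])))
        elif isinstance(geom, MultiPolygon):
            for part in geom.geoms:
                rois.append(ROIPolygon(vertices=tuple(part.exterior.coords[:-1])))
    if not rois:
        raise ValueError("no ROI")
    return rois


def _roi_mask(rois, shape_hw) -> np.ndarray:
    mask = np.zeros(shape_hw, dtype=bool)
    for roi in rois:
        # polygon vertices are (x, y); polygon2mask expects (row, col)
        verts = np.array([(y, x) for x, y in roi.vertices])
        mask |= polygon2mask(shape_hw, verts)
    return mask


def crop_to_rois(slide: SlideImage, rois) -> SlideImage:
    """White-out everything outside the ROI union and crop to its bounding box.

    ROIs extending beyond the slide are clipped with a warning; an empty ROI
    list or a union with zero area inside the slide raises ``ValueError("no
    ROI")``.  The white fill ensures excluded regions also fail the edge QC.
    """
    if not rois:
        raise ValueError("no ROI")
    h, w = slide.shape
    for roi in rois:
        xs, ys = zip(*roi.vertices)
        if min(xs) < 0 or min(ys) < 0 or max(xs) > w or max(ys) > h:
            warnings.warn(f"ROI extends beyond slide bounds for {slide.slide_id}; clipping",
                          stacklevel=2)
            break
    mask = _roi_mask(rois, (h, w))
    if not mask.any():
        raise ValueError("no ROI")
    out = slide.pixels.copy()
    out[~mask] = 255
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    out = out[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    return SlideImage(pixels=out, mpp=slide.mpp, slide_id=slide.slide_id)


def resample_to_mpp(slide: SlideImage, target_mpp: float = TARGET_MPP) -> SlideImage:
    """Bilinear resample so one output pixel spans ``target_mpp`` µm."""
    if target_mpp <= 0:
        raise ValueError("target_mpp must be positive")
    if abs(target_mpp - slide.mpp) < 1e-12:
        return SlideImage(pixels=slide.pixels.copy(), mpp=target_mpp,
                          slide_id=slide.slide_id)
    scale = slide.mpp / target_mpp
    h, w = slide.shape
    out_shape = (max(1, int(round(h * scale))), max(1, int(round(w * scale))))
    resized = sktransform.resize(slide.pixels, out_shape + (3,), order=1,
                                 mode="reflect", anti_aliasing=scale < 1,
                                 preserve_range=True)
    return SlideImage(pixels=np.clip(np.round(resized), 0, 255).astype(np.uint8),
                      mpp=target_mpp, slide_id=slide.slide_id)


def tessellate(slide: SlideImage, tile_px: int = TILE_PX) -> list:
    """Cut the slide into non-overlapping tile_px × tile_px tiles.

    Tiles lie on the regular grid with stride ``tile_px``; partial tiles at
    the right/bottom edge are dropped, so the count is
    floor(H / tile_px) * floor(W / tile_px).
    """
    h, w = slide.shape
    nr, nc = h // tile_px, w // tile_px
    if nr == 0 or nc == 0:
        warnings.warn(f"slide {slide.slide_id} is smaller than one tile; no tiles",
                      stacklevel=2)
        return []
    tiles = []
    for i in range(nr):
        for j in range(nc):
            r, c = i * tile_px, j * tile_px
            tiles.append(Tile(pixels=slide.pixels[r:r + tile_px, c:c + tile_px],
                              origin=(r, c), slide_id=slide.slide_id))
    return tiles


def edge_fraction(tile, canny: CannyParams = CannyParams()) -> float:
    """Fraction of tile pixels marked as edges by the Canny detector."""
    px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    gray = (px.astype(float) @ LUMA) / 255.0
    edges = skfeature.canny(gray, sigma=canny.sigma,
                            low_threshold=canny.low_threshold,
                            high_threshold=canny.high_threshold)
    return float(edges.mean())


def qc_filter(tiles, threshold: float = EDGE_THRESHOLD,
              canny: CannyParams = CannyParams()) -> TileGrid:
    """Discard blank/blurry tiles: kept = tiles with edge fraction >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    slide_id = tiles[0].slide_id if tiles else ""
    kept, kept_ef, disc_o, disc_r, disc_ef = [], [], [], [], []
    for tile in tiles:
        ef = edge_fraction(tile, canny)
        if ef >= threshold:
            kept.append(tile)
            kept_ef.append(ef)
        else:
            disc_o.append(tile.origin)
            disc_r.append("low_edge")
            disc_ef.append(ef)
    if tiles and not kept:
        warnings.warn(f"all tiles of slide {slide_id} discarded (scarce tissue)",
                      stacklevel=2)
    return TileGrid(slide_id=slide_id, tiles=kept,
                    edge_fractions=np.asarray(kept_ef, dtype=np.float32),
                    discarded_origins=disc_o, discarded_reasons=disc_r,
                    discarded_edge_fractions=np.asarray(disc_ef, dtype=np.float32),
                    threshold=threshold)


def save_tile_grid(grid: TileGrid, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        n = len(grid.tiles)
        tiles = np.stack([t.pixels for t in grid.tiles]) if n else \
            np.zeros((0, TILE_PX, TILE_PX, 3), dtype=np.uint8)
        fh.create_dataset("tiles", data=tiles, compression="gzip")
        fh.create_dataset("coords", data=grid.coords)
        fh.create_dataset("edge_fraction", data=grid.edge_fractions)
        fh.attrs["slide_id"] = grid.slide_id
        fh.attrs["threshold"] = grid.threshold


def load_tile_grid(path) -> TileGrid:
    import h5py

    with h5py.File(path, "r") as fh:
        tiles_arr = fh["tiles"][...]
        coords = fh["coords"][...]
        ef = fh["edge_fraction"][...]
        slide_id = fh.attrs["slide_id"]
        threshold = float(fh.attrs["threshold"])
    tiles = [Tile(pixels=tiles_arr[i], origin=tuple(int(v) for v in coords[i]),
                  slide_id=slide_id) for i in range(tiles_arr.shape[0])]
    return TileGrid(slide_id=slide_id, tiles=tiles,
                    edge_fractions=ef.astype(np.float32),
                    discarded_origins=[], discarded_reasons=[],
                    threshold=threshold)
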