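"""Tile-based whole-slide inference: tissue segmentation, tile planning,
batched translation, exact stitching, pyramidal output and QC artifacts.

Coordinate convention everywhere: 0-based, origin at the top-left, tiles are
half-open squares [x, x+size) × [y, y+size) in level-0 pixel units.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from shapely.geometry import Polygon

from .preprocessing import macenko_normalize, otsu_threshold

log = logging.getLogger(__name__)


@dataclasses.dataclass
class TissueSegmentation:
    mask: np.ndarray            # bool, thumbnail resolution
    polygons: list              # shapely Polygons in level-0 coordinates
    scale: float                # level-0 px per mask px
    threshold: float


@dataclasses.dataclass
class SlideTiling:
    slide_id: str
    tile_size: int              # level-0 px (H&E grid)
    origins: list               # [(x, y), ...] level-0, half-open tiles
    overlap: int = 0
    min_tissue_fraction: float = 0.1
    slide_shape: tuple = (0, 0)  # (H, W) level-0

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SlideTiling":
        d = json.loads(Path(path).read_text())
        d["origins"] = [tuple(o) for o in d["origins"]]
        d["slide_shape"] = tuple(d["slide_shape"])
        return cls(**d)


def segment_tissue(thumbnail: np.ndarray, scale: float = 1.0,
                   min_object_px: int = 64) -> TissueSegmentation:
    """Otsu foreground segmentation of stained tissue on a white background.

    Works on inverted luminance (stain absorbs light, so tissue is darker);
    small specks are removed and holes closed before contour extraction.
    """
    thumb = np.asarray(thumbnail, dtype=np.float64)
    if thumb.max() > 1.0 + 1e-9:
        thumb = thumb / 255.0
    gray = 1.0 - thumb.mean(axis=2) if thumb.ndim == 3 else 1.0 - thumb
    try:
        thr = otsu_threshold(gray)
    except ValueError:
        raise ValueError("no tissue found: thumbnail is constant")
    mask = gray > thr
    if not mask.any():
        raise ValueError("no tissue found")
    mask = morphology.remove_small_objects(mask, max_size=min_object_px)
    mask = ndimage.binary_fill_holes(morphology.closing(
        mask, morphology.disk(2)))
    if not mask.any():
        raise ValueError("no tissue found after cleanup")
    polys = []
    padded = np.pad(mask.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        pts = (contour[:, ::-1] - 1.0) * scale  # (y,x) -> (x,y), level-0 units
        if len(pts) >= 4:
            poly = Polygon(pts)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    return TissueSegmentation(mask=mask, polygons=polys, scale=scale,
                              threshold=float(thr))


def plan_tiles(mask: np.ndarray, tile_size: int,
               min_tissue_fraction: float = 0.1, mask_scale: int = 1,
               overlap: int = 0, slide_id: str = "slide") -> SlideTiling:
    """Grid tiles kept iff their tissue fraction reaches the threshold.

    `mask_scale` is level-0 px per mask px and must divide the tile size so
    fractions are exact.  Fractions are computed with a summed-area table.
    """
    if tile_size % mask_scale:
        raise ValueError("tile_size must be a multiple of mask_scale")
    t = tile_size // mask_scale
    step = t - overlap // mask_scale
    if step <= 0:
        raise ValueError("overlap too large")
    h, w = mask.shape
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), 0), 1)
    origins = []
    for y0 in range(0, h - t + 1, step):
        for x0 in range(0, w - t + 1, step):
            count = (sat[y0 + t, x0 + t] - sat[y0, x0 + t]
                     - sat[y0 + t, x0] + sat[y0, x0])
            frac = count / (t * t)
            if frac >= min_tissue_fraction:
                origins.append((x0 * mask_scale, y0 * mask_scale))
    return SlideTiling(slide_id=slide_id, tile_size=tile_size, origins=origins,
                       overlap=overlap, min_tissue_fraction=min_tissue_fraction,
                       slide_shape=(h * mask_scale, w * mask_scale))


@dataclasses.dataclass
class InferenceResult:
    stack: np.ndarray           # (C, H/f, W/f) stitched marker prediction
    pyramid: list               # successive 2x-downsampled levels incl. level 0
    qc_image: np.ndarray        # thumbnail with tile grid overlay
    holes: list                 # origins of tiles that failed


def run_inference(slide: np.ndarray, tiling: SlideTiling, model,
                  out_scale_factor: int = 4, batch_size: int = 4,
                  stain_norm: bool = False, n_pyramid_levels: int = 3,
                  training_minmax: tuple | None = None) -> InferenceResult:
    """Translate every planned tile and stitch onto the marker grid.

    `model` maps a (B, 3, t, t) H&E batch to (B, C, t/f, t/f) marker
    predictions (a `Translator` is adapted automatically).  Non-tissue
    regions stay zero.  Failing tiles are logged, skipped and reported as
    holes.  With overlap > 0 overlapping predictions are feather-blended;
    for overlap 0 stitching is exact.
    """
    f = out_scale_factor
    t = tiling.tile_size
    sh, sw = slide.shape[:2]
    if t % f:
        raise ValueError("tile size must be divisible by the scale factor")
    model_fn = _as_model_fn(model)
    n_ch = None
    out = None
    weight = None
    holes = []
    origins = list(tiling.origins)
    for i in range(0, len(origins), batch_size):
        batch_orig = origins[i:i + batch_size]
        tiles, kept = [], []
        for (x0, y0) in batch_orig:
            try:
                tile = np.asarray(slide[y0:y0 + t, x0:x0 + t], dtype=np.float64)
                if tile.shape[:2] != (t, t):
                    raise ValueError("tile outside slide bounds")
                if tile.max() > 1.0 + 1e-9:
                    tile = tile / 255.0
                if stain_norm:
                    tile = macenko_normalize(tile)
                tiles.append(np.transpose(tile, (2, 0, 1)))
                kept.append((x0, y0))
            except Exception as exc:  # noqa: BLE001 - holes are recorded in QC
                log.warning("tile (%d, %d) failed: %s", x0, y0, exc)
                holes.append((x0, y0))
        if not tiles:
            continue
        preds = model_fn(np.stack(tiles))
        if n_ch is None:
            n_ch = preds.shape[1]
            out = np.zeros((n_ch, sh // f, sw // f))
            weight = np.zeros((sh // f, sw // f))
        for pred, (x0, y0) in zip(preds, kept):
            ox, oy = x0 // f, y0 // f
            tf = t // f
            if tiling.overlap == 0:
                out[:, oy:oy + tf, ox:ox + tf] = pred
                weight[oy:oy + tf, ox:ox + tf] = 1.0
            else:
                wgt = _feather(tf, tiling.overlap // f)
                out[:, oy:oy + tf, ox:ox + tf] += pred * wgt
                weight[oy:oy + tf, ox:ox + tf] += wgt
    if out is None:
        log.warning("empty tile plan: producing empty output")
        out = np.zeros((0, sh // f, sw // f))
        weight = np.zeros((sh // f, sw // f))
    elif tiling.overlap > 0:
        nz = weight > 0
        out[:, nz] /= weight[nz]
    if training_minmax is not None:
        lo, hi = training_minmax
        out = np.clip((out - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    pyramid = build_pyramid(out, n_pyramid_levels)
    qc = _qc_overlay(slide, tiling, holes)
    return InferenceResult(stack=out, pyramid=pyramid, qc_image=qc, holes=holes)


def _as_model_fn(model):
    if callable(model) and not hasattr(model, "forward"):
        return model
    from .nn import autograd as ag
    from .nn.autograd import Tensor

    def fn(batch):
        model.eval()
        with ag.no_grad():
            outs = model(Tensor(batch))
        model.train()
        return outs[1.0].data

    return fn


def _feather(tile: int, overlap: int) -> np.ndarray:
    if overlap <= 0:
        return np.ones((tile, tile))
    ramp = np.ones(tile)
    edge = np.linspace(1.0 / (overlap + 1), 1.0, overlap, endpoint=False)
    ramp[:overlap] = edge
    ramp[-overlap:] = edge[::-1]
    return np.outer(ramp, ramp)


def build_pyramid(stack: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Level L has level-0 dimensions divided by 2^L (2x2 block means)."""
    levels = [stack]
    cur = stack
    for _ in range(n_levels - 1):
        c, h, w = cur.shape
        if min(h, w) < 2:
            break
        cur = cur[:, :h - h % 2, :w - w % 2].reshape(
            c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
        levels.append(cur)
    return levels


def write_pyramidal_tiff(path: str | Path, pyramid: list[np.ndarray],
                         channels: list[str] | None = None):
    import tifffile
    meta = {"channels": channels} if channels else {}
    with tifffile.TiffWriter(path) as tif:
        tif.write(pyramid[0].astype(np.float32), subifds=len(pyramid) - 1,
                  metadata=meta)
        for lvl in pyramid[1:]:
            tif.write(lvl.astype(np.float32), subfiletype=1)


def _qc_overlay(slide: np.ndarray, tiling: SlideTiling,
                holes: list) -> np.ndarray:
    qc = np.asarray(slide, dtype=np.float64).copy()
    if qc.max() > 1.0 + 1e-9:
        qc = qc / 255.0
    t = tiling.tile_size
    hole_set = set(holes)
    for (x0, y0) in tiling.origins:
        color = np.array([1.0, 0.0, 0.0]) if (x0, y0) in hole_set \
            else np.array([0.0, 0.8, 0.0])
        qc[y0, x0:x0 + t] = color
        qc[min(y0 + t - 1, qc.shape[0] - 1), x0:x0 + t] = color
        qc[y0:y0 + t, x0] = color
        qc[y0:y0 + t, min(x0 + t - 1, qc.shape[1] - 1)] = color
    return qc
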