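"""Resizing and CLAHE contrast enhancement.

Resizing is bilinear via Pillow and assumes square inputs (the working
data are 1:1 CT exports), so no cropping or aspect distortion occurs.
CLAHE follows the classical recipe: per-tile 256-bin histograms clipped
at a limit expressed as a multiple of the mean bin count, the clipped
excess redistributed uniformly, per-tile equalization mappings blended
bilinearly between tile centers.  Identical preprocessing is applied to
every split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dataset import CTSlice, DatasetManifest, SegMask, load_mask, load_slice, save_mask, save_slice


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE settings.

    ``clip_limit`` caps each tile-histogram bin at ``clip_limit`` times
    the tile's mean bin count before equalization; ``tile_grid`` is the
    (rows, cols) tiling of the image.  Defaults are the conventional
    2.0 / 8x8.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if min(self.tile_grid) < 1:
            raise ValueError("tile_grid entries must be >= 1")


def resize_slice(ct: CTSlice, target: int) -> CTSlice:
    """Bilinearly resize a square slice to ``target`` x ``target``."""
    if target < 32:
        raise ValueError(f"target size must be >= 32, got {target}")
    if ct.height != ct.width:
        raise ValueError(
            f"expected a square slice, got {ct.height}x{ct.width}"
        )
    im = Image.fromarray(ct.pixels, mode="L")
    out = im.resize((target, target), Image.Resampling.BILINEAR)
    return CTSlice(
        pixels=np.asarray(out), patient_id=ct.patient_id, slice_index=ct.slice_index
    )


def resize_mask(mask: SegMask, target: int) -> SegMask:
    """Nearest-neighbor resize of a label mask (labels must stay integral)."""
    im = Image.fromarray(mask.labels, mode="L")
    out = im.resize((target, target), Image.Resampling.NEAREST)
    return SegMask(labels=np.asarray(out), legend=dict(mask.legend))


def clip_histogram(hist: np.ndarray, clip_count: int) -> np.ndarray:
    """Clip a histogram at ``clip_count`` and redistribute the excess evenly.

    The uniform share goes to every bin, the integer remainder to the
    lowest bins, so no bin ends above ``clip_count + excess // nbins + 1``.
    """
    hist = hist.astype(np.int64).copy()
    excess = int(np.maximum(hist - clip_count, 0).sum())
    np.minimum(hist, clip_count, out=hist)
    if excess:
        share, rem = divmod(excess, hist.size)
        hist += share
        hist[:rem] += 1
    return hist


def _tile_luts(tiles: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization lookup tables per tile; ``tiles`` is (gr, gc, th, tw)."""
    gr, gc, th, tw = tiles.shape
    n_pix = th * tw
    clip_count = max(1, int(clip_limit * n_pix / 256.0))
    luts = np.empty((gr, gc, 256), dtype=np.uint8)
    for r in range(gr):
        for c in range(gc):
            hist = np.bincount(tiles[r, c].ravel(), minlength=256)
            hist = clip_histogram(hist, clip_count)
            cdf = np.cumsum(hist)
            luts[r, c] = np.rint(cdf * 255.0 / cdf[-1]).astype(np.uint8)
    return luts


def apply_clahe(ct: CTSlice, params: ClaheParams = ClaheParams()) -> CTSlice:
    """Contrast-limited adaptive histogram equalization of an 8-bit slice."""
    h, w = ct.pixels.shape
    gr, gc = params.tile_grid
    if gr > h or gc > w:
        raise ValueError(
            f"tile grid {params.tile_grid} larger than image {h}x{w}"
        )
    th = -(-h // gr)  # ceil division; border tiles handled by reflect padding
    tw = -(-w // gc)
    padded = np.pad(ct.pixels, ((0, gr * th - h), (0, gc * tw - w)), mode="reflect")
    tiles = padded.reshape(gr, th, gc, tw).transpose(0, 2, 1, 3)
    luts = _tile_luts(tiles, params.clip_limit)

    # blend the four surrounding tile mappings bilinearly between tile centers
    yy, xx = np.mgrid[:h, :w]
    ty = (yy + 0.5) / th - 0.5
    tx = (xx + 0.5) / tw - 0.5
    r0 = np.clip(np.floor(ty).astype(np.int64), 0, gr - 1)
    c0 = np.clip(np.floor(tx).astype(np.int64), 0, gc - 1)
    r1 = np.minimum(r0 + 1, gr - 1)
    c1 = np.minimum(c0 + 1, gc - 1)
    wy = np.clip(ty - r0, 0.0, 1.0)
    wx = np.clip(tx - c0, 0.0, 1.0)

    v = ct.pixels
    out = (
        (1 - wy) * (1 - wx) * luts[r0, c0, v]
        + (1 - wy) * wx * luts[r0, c1, v]
        + wy * (1 - wx) * luts[r1, c0, v]
        + wy * wx * luts[r1, c1, v]
    )
    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return CTSlice(pixels=pixels, patient_id=ct.patient_id, slice_index=ct.slice_index)


def to_network_input(pixels: np.ndarray) -> np.ndarray:
    """Scale 8-bit pixels to [0, 1] and replicate to the 3-channel layout
    the network declares (C, H, W) float32."""
    x = pixels.astype(np.float32) / 255.0
    return np.repeat(x[None, :, :], 3, axis=0)


def preprocess_manifest(
    manifest: DatasetManifest,
    out_dir: str | Path,
    target_size: int = 256,
    clahe: ClaheParams | None = ClaheParams(),
) -> DatasetManifest:
    """Resize (and optionally CLAHE-enhance) every slice and mask in a
    manifest, writing results under ``out_dir`` and returning the updated
    manifest.  All splits receive identical preprocessing."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    rows = []
    for _, row in manifest.frame.iterrows():
        ct = load_slice(row["image_path"], patient_id=row["patient_id"])
        if ct.height != target_size:
            ct = resize_slice(ct, target_size)
        if clahe is not None:
            ct = apply_clahe(ct, clahe)
        new_img = img_dir / Path(row["image_path"]).name
        save_slice(ct, new_img)
        new_row = dict(row)
        new_row["image_path"] = str(new_img)
        if row["mask_path"]:
            mask = load_mask(row["mask_path"])
            if mask.labels.shape[0] != target_size:
                mask = resize_mask(mask, target_size)
            new_mask = mask_dir / Path(row["mask_path"]).name
            save_mask(mask, new_mask)
            new_row["mask_path"] = str(new_mask)
        rows.append(new_row)
    return DatasetManifest(pd.DataFrame(rows))
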