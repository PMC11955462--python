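"""Tiling of slide-scale images into 224x224 patches, background filtering
by a whiteness threshold, and ImageNet-style channel normalization.

H&E background is near-white, so a patch's tissue content is measured as
the fraction of pixels whose mean RGB value falls strictly below a
whiteness cutoff (default 220); patches with less than 5% tissue are
discarded before training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PATCH_SIZE = 224
#: per-channel RGB normalization constants (pixel/255 scale)
NORM_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
NORM_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

DEFAULT_WHITENESS_CUTOFF = 220
DEFAULT_MIN_TISSUE_FRACTION = 0.05


@dataclass
class PatchRecord:
    """One 224x224 RGB patch with provenance back to its source tile."""

    patch_id: str
    source_id: str
    grid_row: int
    grid_col: int
    pixels: np.ndarray  # (224, 224, 3) uint8
    tissue_fraction: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(f"patch pixels must be 224x224x3, got {self.pixels.shape}")


def tile_image(image: np.ndarray, source_id: str = "tile",
               tile_size: int = PATCH_SIZE, stride: int = PATCH_SIZE) -> list[PatchRecord]:
    """Cut an HxWx3 uint8 image into a row-major grid of patches.

    Partial border windows are dropped; patch (r, c) covers the half-open
    pixel window [r*stride, r*stride + tile_size) x [c*stride, ...).
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than tile size {tile_size}")
    records = []
    for r in range((h - tile_size) // stride + 1):
        for c in range((w - tile_size) // stride + 1):
            px = image[r * stride: r * stride + tile_size,
                       c * stride: c * stride + tile_size]
            rec = PatchRecord(
                patch_id=f"{source_id}_r{r}_c{c}",
                source_id=source_id, grid_row=r, grid_col=c,
                pixels=np.ascontiguousarray(px),
            )
            rec.tissue_fraction = tissue_fraction(rec)
            records.append(rec)
    return records


def tissue_fraction(patch: PatchRecord | np.ndarray,
                    whiteness_cutoff: float = DEFAULT_WHITENESS_CUTOFF) -> float:
    """Fraction of pixels whose mean RGB is strictly below the cutoff."""
    px = patch.pixels if isinstance(patch, PatchRecord) else patch
    mean_rgb = px.astype(np.float32).mean(axis=2)
    return float((mean_rgb < whiteness_cutoff).mean())


def filter_background(patches: list[PatchRecord],
                      min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION) -> list[PatchRecord]:
    """Keep patches with tissue_fraction >= min_tissue_fraction, in order."""
    kept = [p for p in patches if p.tissue_fraction >= min_tissue_fraction]
    log.info("background filter: kept %d/%d patches (min tissue fraction %.3f)",
             len(kept), len(patches), min_tissue_fraction)
    return kept


def normalize_patch(patch: PatchRecord | np.ndarray) -> np.ndarray:
    """(224,224,3) uint8 -> (3,224,224) float32, (x/255 - mean)/std per channel."""
    px = patch.pixels if isinstance(patch, PatchRecord) else patch
    x = px.astype(np.float32) / 255.0
    x = (x - NORM_MEAN) / NORM_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def denormalize(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_patch`, returning pixel/255 floats."""
    return values.transpose(1, 2, 0) * NORM_STD + NORM_MEAN


def patch_manifest(patches: list[PatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patch_id": p.patch_id, "source_id": p.source_id, "grid_row": p.grid_row,
          "grid_col": p.grid_col, "tissue_fraction": p.tissue_fraction}
         for p in patches]
    )
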