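"""Microglial surveillance and motility from binarised mask stacks.

Microglia continuously extend and retract processes; the surveillance
index S(t) is the cumulative number of distinct pixels the binarised cell
mask has covered up to frame t (S(0) equals the cell area at t = 0).  The
motility index divides S(t) by the cell area so that big cells are not
scored as more motile merely for being big; a perfectly static cell has
motility 1 at every frame.  The Methods convention normalises by the
per-frame area; the area of the maximum-intensity projection is also
reported because a projection-based area is the other common reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class MaskStack:
    """Time series of binary cell masks (frames, height, width)."""

    frames: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 60.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames)
        if fr.ndim != 3 or fr.shape[0] < 2:
            raise ValueError("mask stack must be (>=2 frames, H, W)")
        vals = np.unique(fr)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValueError("masks must be binary (0/1 or 0/255)")
        object.__setattr__(self, "frames", fr > 0)
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")


@dataclass(frozen=True)
class SurveillanceResult:
    cumulative_pixels: np.ndarray   # S(t), nondecreasing
    cell_area: np.ndarray           # per-frame mask area (pixels)
    motility_index: np.ndarray      # S(t) / area(t)
    projection_area: int            # area of the max-intensity projection
    motility_index_projection: np.ndarray  # S(t) / projection area


def surveillance_curve(stack: MaskStack) -> SurveillanceResult:
    """Cumulative surveilled-pixel curve and motility index per frame."""
    if not stack.frames[0].any():
        raise ValueError("mask at t=0 is empty: no cell to track")
    union = np.logical_or.accumulate(stack.frames, axis=0)
    s = union.sum(axis=(1, 2)).astype(np.int64)
    area = stack.frames.sum(axis=(1, 2)).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        motility = np.where(area > 0, s / area, np.nan)
    proj_area = int(s[-1])
    return SurveillanceResult(
        cumulative_pixels=s,
        cell_area=area,
        motility_index=motility,
        projection_area=proj_area,
        motility_index_projection=s / proj_area,
    )


def compare_surveillance(
    group_a: list[SurveillanceResult], group_b: list[SurveillanceResult]
) -> pd.DataFrame:
    """Per-frame group means ± SE of the surveillance curves and their
    difference (a - b).  Curves are truncated to the shortest record."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    n_frames = min(r.cumulative_pixels.size for r in group_a + group_b)
    a = np.stack([r.cumulative_pixels[:n_frames] for r in group_a]).astype(float)
    b = np.stack([r.cumulative_pixels[:n_frames] for r in group_b]).astype(float)

    def se(x):
        return x.std(axis=0, ddof=1) / np.sqrt(x.shape[0]) if x.shape[0] > 1 else np.zeros(n_frames)

    return pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "mean_a": a.mean(axis=0),
            "se_a": se(a),
            "mean_b": b.mean(axis=0),
            "se_b": se(b),
            "difference": a.mean(axis=0) - b.mean(axis=0),
        }
    )


def binarize_otsu(images: np.ndarray) -> np.ndarray:
    """Convenience Otsu binariser for raw intensity stacks (one global
    threshold across the stack, as for a stable imaging session)."""
    images = np.asarray(images)
    thr = threshold_otsu(images)
    return images > thr


def read_mask_stack(
    path, pixel_size_um: float = 1.0, frame_interval_s: float = 60.0
) -> MaskStack:
    """Read a multi-page TIFF of binary masks (uint8, 0/255 or 0/1)."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return MaskStack(frames, pixel_size_um, frame_interval_s)


def write_mask_stack(path, stack: MaskStack) -> None:
    tifffile.imwrite(path, (stack.frames.astype(np.uint8) * 255))
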