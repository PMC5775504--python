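"""Mask-based motility metrics: sampling efficiency and protrusion index.

Sampling efficiency over a window of ``n_steps`` frames is the number of
unique foreground pixels (the union of visited pixels) divided by the summed
per-frame foreground counts; a stationary footprint gives ``1/n_steps`` and
pairwise-disjoint footprints give 1.

The per-frame fractional overlap of a cell with its spot is
``f = (cell ∩ spot) / cell``; the maximum possible overlap is
``m = min(1, spot_area / cell_area)`` and the protrusion index is ``m - f``.
All areas use rasterized pixel counts at the mask resolution, so the bounds
``0 <= f <= m <= 1`` hold exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trackcore import MaskSeries, SpotGrid

__all__ = [
    "DEFAULT_N_STEPS",
    "SamplingResult",
    "OverlapMetrics",
    "ContourSummary",
    "rasterize_spot",
    "sampling_efficiency",
    "mean_sampling_efficiency",
    "protrusion_index",
    "overlap_contour",
]

logger = logging.getLogger(__name__)

DEFAULT_N_STEPS = 20


@dataclass
class SamplingResult:
    """Sampling efficiency of one sliding window of mask frames."""

    start: int  # index of first frame in the window
    n_steps: int
    unique_pixels: int
    total_pixels: int

    @property
    def efficiency(self) -> float:
        return self.unique_pixels / self.total_pixels


@dataclass
class OverlapMetrics:
    """Per-frame overlap of a cell mask with one spot disk."""

    frames: np.ndarray
    cell_area: np.ndarray  # μm²
    overlap_area: np.ndarray  # μm²
    fractional_overlap: np.ndarray
    max_possible_overlap: np.ndarray
    protrusion_index: np.ndarray
    spot_area: float  # μm² (rasterized)

    def __post_init__(self) -> None:
        f, m = self.fractional_overlap, self.max_possible_overlap
        if np.any(f < -1e-12) or np.any(f > m + 1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("overlap bounds violated: require 0 <= f <= m <= 1")


@dataclass
class ContourSummary:
    """Pooled (cell_area/spot_area, fractional overlap) density with m trace."""

    area_ratio: np.ndarray  # pooled per-frame points
    fractional_overlap: np.ndarray
    hist: np.ndarray
    ratio_edges: np.ndarray
    overlap_edges: np.ndarray
    trace_ratio: np.ndarray
    trace_m: np.ndarray


def rasterize_spot(grid: SpotGrid, spot_id: int, masks: MaskSeries) -> np.ndarray:
    """Boolean raster of one spot disk at the mask resolution.

    Pixel-center inclusion: pixel (r, c) is foreground iff its centre lies
    within the spot radius of the spot centre.
    """
    _, h, w = masks.masks.shape
    cx, cy = grid.centers[spot_id]
    x = masks.origin[0] + masks.pixel_size * np.arange(w)
    y = masks.origin[1] + masks.pixel_size * np.arange(h)
    xx, yy = np.meshgrid(x, y)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= grid.radius**2


def sampling_efficiency(
    masks: MaskSeries, n_steps: int = DEFAULT_N_STEPS, stride: int = 1
) -> list[SamplingResult]:
    """Sampling efficiency for every sliding window of ``n_steps`` frames.

    Windows containing an empty mask are skipped (logged).  Requires at least
    ``n_steps`` frames.
    """
    n = len(masks)
    if n < n_steps:
        raise ValueError(f"need >= {n_steps} mask frames, got {n}")
    counts = masks.masks.sum(axis=(1, 2))
    results: list[SamplingResult] = []
    for start in range(0, n - n_steps + 1, stride):
        window_counts = counts[start : start + n_steps]
        if np.any(window_counts == 0):
            logger.info("skipping window at %d: empty mask inside", start)
            continue
        union = masks.masks[start : start + n_steps].any(axis=0)
        results.append(
            SamplingResult(
                start=start,
                n_steps=n_steps,
                unique_pixels=int(union.sum()),
                total_pixels=int(window_counts.sum()),
            )
        )
    return results


def mean_sampling_efficiency(masks: MaskSeries, n_steps: int = DEFAULT_N_STEPS, stride: int = 1) -> float:
    """Track-level sampling efficiency: mean over sliding windows."""
    results = sampling_efficiency(masks, n_steps=n_steps, stride=stride)
    if not results:
        raise ValueError("no usable windows")
    return float(np.mean([r.efficiency for r in results]))


def protrusion_index(masks: MaskSeries, grid: SpotGrid, spot_id: int) -> OverlapMetrics:
    """Per-frame fractional overlap, max possible overlap, and protrusion index.

    Empty mask frames are skipped.
    """
    spot = rasterize_spot(grid, spot_id, masks)
    spot_px = int(spot.sum())
    if spot_px == 0:
        raise ValueError("spot raster empty at this resolution/extent")
    keep = ~masks.empty
    if not keep.any():
        raise ValueError("all mask frames empty")
    sub = masks.masks[keep]
    cell_px = sub.sum(axis=(1, 2))
    overlap_px = (sub & spot).sum(axis=(1, 2))
    f = overlap_px / cell_px
    m = np.minimum(1.0, spot_px / cell_px)
    px_area = masks.pixel_size**2
    return OverlapMetrics(
        frames=masks.frames[keep],
        cell_area=cell_px * px_area,
        overlap_area=overlap_px * px_area,
        fractional_overlap=f,
        max_possible_overlap=m,
        protrusion_index=m - f,
        spot_area=spot_px * px_area,
    )


def overlap_contour(
    metrics: Sequence[OverlapMetrics],
    ratio_bins: int = 40,
    overlap_bins: int = 40,
    max_ratio: float | None = None,
) -> ContourSummary:
    """Pool per-frame (area ratio, fractional overlap) points across cells.

    Emits a 2D histogram plus the maximum-possible-overlap boundary trace
    ``m(ratio) = min(1, 1/ratio)``.  Needs at least two cells.
    """
    if len(metrics) < 2:
        raise ValueError("need metrics from >= 2 cells")
    ratios = np.concatenate([m.cell_area / m.spot_area for m in metrics])
    f = np.concatenate([m.fractional_overlap for m in metrics])
    if max_ratio is None:
        max_ratio = float(ratios.max()) * 1.05
    hist, re, oe = np.histogram2d(
        ratios, f, bins=[ratio_bins, overlap_bins], range=[[0, max_ratio], [0, 1]]
    )
    trace_ratio = np.linspace(1e-6, max_ratio, 200)
    trace_m = np.minimum(1.0, 1.0 / trace_ratio)
    return ContourSummary(
        area_ratio=ratios,
        fractional_overlap=f,
        hist=hist,
        ratio_edges=re,
        overlap_edges=oe,
        trace_ratio=trace_ratio,
        trace_m=trace_m,
    )
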