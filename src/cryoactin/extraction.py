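"""Simplified filament detection from fluorescence images.

A deliberately lightweight stand-in for dedicated filament-tracing
software: it recovers per-filament length, width, orientation and position
from rendered or acquired images of bright line-like structures on a dark
background.  The pipeline is

    ridge enhancement (Hessian-based line filter)
      -> binarization (configurable threshold strategy)
      -> skeletonization
      -> junction removal and 8-connected path tracing
      -> splitting of traced paths into straight segments wherever the
         local direction change exceeds a curvature threshold
      -> per-segment measurement.

Per segment: length is the end-to-end chord length, orientation the chord
angle to the horizontal folded to [0, 180) degrees, width twice the mean
distance-transform value along the segment (with a half-pixel-per-side
discretization correction), position the chord midpoint.  Segments shorter
than a minimum or dimmer than a minimum mean intensity are discarded.
Crossing filaments are fragmented at junctions — an accepted limitation of
the junction-removal tracing strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage
from skimage.filters import sato, threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from .metrics import FilamentSet

__all__ = ["ExtractionConfig", "max_intensity_projection", "extract_filaments"]


@dataclass(frozen=True)
class ExtractionConfig:
    pixel_size_um: float = 0.1
    ridge_scale_px: float = 1.5
    threshold: Union[str, float] = "otsu"   # "otsu", "half_max" or absolute value
    min_segment_length_px: float = 5.0
    max_curvature_per_step_deg: float = 20.0
    min_mean_intensity: float = 5.0         # on the image's own intensity scale
    trace_step_px: int = 7                  # lookahead for local path direction
    ridge_rel_threshold: float = 0.05       # ridge response gate, fraction of max
    width_correction_px: float = 0.5        # center-to-center DT discretization bias

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.ridge_scale_px <= 0:
            raise ValueError("pixel_size_um and ridge_scale_px must be > 0")
        if self.min_segment_length_px <= 0 or self.max_curvature_per_step_deg <= 0:
            raise ValueError("segment-splitting parameters must be > 0")
        if self.min_mean_intensity < 0:
            raise ValueError("min_mean_intensity must be >= 0")
        if self.trace_step_px < 1:
            raise ValueError("trace_step_px must be >= 1")


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Collapse a z-stack to 2D by the per-pixel maximum across planes."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D image or 3D stack, got ndim={arr.ndim}")
    if arr.shape[0] == 0:
        raise ValueError("empty stack")
    return arr.max(axis=0)


def _binarize(img: np.ndarray, cfg: ExtractionConfig) -> np.ndarray:
    if isinstance(cfg.threshold, str):
        if cfg.threshold == "otsu":
            thr = threshold_otsu(img)
        elif cfg.threshold == "half_max":
            bg = float(np.median(img))
            thr = bg + 0.5 * (float(img.max()) - bg)
        else:
            raise ValueError(f"unknown threshold strategy {cfg.threshold!r}")
    else:
        thr = float(cfg.threshold)
    return img > thr


def _trace_paths(skel: np.ndarray) -> list:
    """Ordered pixel paths from a skeleton; junction pixels are removed first
    so every remaining component is a simple path."""
    nbr_kernel = np.ones((3, 3)); nbr_kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), nbr_kernel, mode="constant")
    simple = skel & (nbrs <= 2)
    lbl, nlab = label(simple, connectivity=2, return_num=True)
    paths = []
    for k in range(1, nlab + 1):
        coords = np.argwhere(lbl == k)
        if len(coords) < 2:
            continue
        pset = {tuple(p) for p in coords}
        deg = {}
        for (r, c) in pset:
            deg[(r, c)] = sum(((r + dr, c + dc) in pset)
                              for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                              if (dr, dc) != (0, 0))
        ends = sorted(p for p, d in deg.items() if d == 1)
        start = ends[0] if ends else sorted(pset)[0]
        path = [start]
        visited = {start}
        cur = start
        while True:
            r, c = cur
            nxt = None
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    cand = (r + dr, c + dc)
                    if cand in pset and cand not in visited:
                        # prefer 4-connected continuation for smoother paths
                        if nxt is None or abs(dr) + abs(dc) < abs(nxt[0] - r) + abs(nxt[1] - c):
                            nxt = cand
            if nxt is None:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        if len(path) >= 2:
            paths.append(np.array(path))
    return paths


def _split_at_bends(points: np.ndarray, max_turn_deg: float, step: int) -> list:
    """Cut an ordered path wherever the direction over a `step`-pixel window
    turns by more than max_turn_deg."""
    n = len(points)
    if n <= 2 * step + 1:
        return [points]
    segs = []
    start = 0
    i = step
    while i < n - step:
        v1 = points[i] - points[i - step]
        v2 = points[i + step] - points[i]
        a1 = math.degrees(math.atan2(v1[0], v1[1]))
        a2 = math.degrees(math.atan2(v2[0], v2[1]))
        turn = (a2 - a1 + 180.0) % 360.0 - 180.0
        if abs(turn) > max_turn_deg:
            segs.append(points[start:i + 1])
            start = i
            i += step          # skip past the corner neighbourhood
        else:
            i += 1
    segs.append(points[start:])
    return [s for s in segs if len(s) >= 2]


def extract_filaments(image: np.ndarray, cfg: ExtractionConfig = ExtractionConfig(),
                      cell_id: str = "") -> FilamentSet:
    """Detect straight filament segments in a grayscale image.

    Returns a FilamentSet with lengths/widths/positions in um (centroids
    relative to the image center) and orientations in [0, 180) degrees.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={img.ndim}")
    empty = FilamentSet(cell_id=cell_id)
    if img.max() == img.min():
        return empty

    enhanced = sato(img, sigmas=[cfg.ridge_scale_px], black_ridges=False)
    binary = _binarize(img, cfg)
    if enhanced.max() > 0:
        binary &= enhanced > cfg.ridge_rel_threshold * enhanced.max()
    if not binary.any():
        return empty

    skel = skeletonize(binary)
    dt = ndimage.distance_transform_edt(binary)
    rows, cols = img.shape
    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0

    L, W, T, X, Y = [], [], [], [], []
    for path in _trace_paths(skel):
        for seg in _split_at_bends(path, cfg.max_curvature_per_step_deg, cfg.trace_step_px):
            p0, p1 = seg[0], seg[-1]
            chord_px = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
            if chord_px < cfg.min_segment_length_px:
                continue
            vals = img[seg[:, 0], seg[:, 1]]
            if vals.mean() < cfg.min_mean_intensity:
                continue
            width_px = 2.0 * float(dt[seg[:, 0], seg[:, 1]].mean()) - cfg.width_correction_px
            width_px = max(width_px, 0.5)
            theta = math.degrees(math.atan2(p1[0] - p0[0], p1[1] - p0[1])) % 180.0
            L.append(chord_px * cfg.pixel_size_um)
            W.append(width_px * cfg.pixel_size_um)
            T.append(theta)
            X.append(((p0[1] + p1[1]) / 2.0 - cx0) * cfg.pixel_size_um)
            Y.append(((p0[0] + p1[0]) / 2.0 - cy0) * cfg.pixel_size_um)
    return FilamentSet(cell_id=cell_id, lengths_um=np.array(L), widths_um=np.array(W),
                       thetas_deg=np.array(T), x_um=np.array(X), y_um=np.array(Y))
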