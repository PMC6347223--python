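"""Rasterize ground-truth filament networks into synthetic fluorescence images.

Each filament is drawn as an anti-aliased line of its physical width
(smooth capsule coverage profile), the frame is convolved with a Gaussian
point-spread function, and Poisson-Gaussian acquisition noise plus a
constant background are added.  Coordinates: image origin top-left, x
rightward (columns), y downward (rows), pixel centers at integer
coordinates; orientations are measured from the +x axis and folded to
[0, 180) degrees, matching the extraction stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .metrics import FilamentSet

__all__ = ["RenderConfig", "render_image"]


@dataclass(frozen=True)
class RenderConfig:
    pixel_size_um: float = 0.1      # um per pixel
    psf_sigma_px: float = 0.8       # Gaussian PSF width
    image_shape: tuple = (768, 768)  # rows, cols
    amplitude: float = 180.0        # peak filament signal, a.u.
    background: float = 2.0
    poisson_noise: bool = False
    read_noise_sd: float = 0.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.psf_sigma_px < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("psf/background/noise parameters must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


def _dtype(rc: RenderConfig):
    return np.uint8 if rc.bit_depth == 8 else np.uint16


def render_image(fs: FilamentSet, rc: RenderConfig = RenderConfig(), seed=None):
    """Render a filament set; returns (image, ground_truth_frame).

    Filament centroids are in um relative to the image center.  Filaments
    extending outside the frame raise a warning and are clipped by the
    frame boundary.
    """
    rows, cols = rc.image_shape
    img = np.zeros((rows, cols), dtype=float)
    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]

    for i in range(fs.n):
        l_px = fs.lengths_um[i] / rc.pixel_size_um
        w_px = fs.widths_um[i] / rc.pixel_size_um
        t = math.radians(fs.thetas_deg[i])
        ux, uy = math.cos(t), math.sin(t)
        cx = cx0 + fs.x_um[i] / rc.pixel_size_um
        cy = cy0 + fs.y_um[i] / rc.pixel_size_um
        x0, y0 = cx - l_px / 2 * ux, cy - l_px / 2 * uy
        x1, y1 = cx + l_px / 2 * ux, cy + l_px / 2 * uy
        if not (0 <= min(x0, x1) and max(x0, x1) < cols and 0 <= min(y0, y1) and max(y0, y1) < rows):
            warnings.warn(f"filament {i} extends outside the image and is clipped",
                          stacklevel=2)
        pad = w_px / 2 + 2
        rlo = max(int(min(y0, y1) - pad), 0)
        rhi = min(int(max(y0, y1) + pad) + 1, rows)
        clo = max(int(min(x0, x1) - pad), 0)
        chi = min(int(max(x0, x1) + pad) + 1, cols)
        if rlo >= rhi or clo >= chi:
            continue
        px = xx[rlo:rhi, clo:chi].astype(float)
        py = yy[rlo:rhi, clo:chi].astype(float)
        # distance from each pixel center to the centerline segment
        vx, vy = x1 - x0, y1 - y0
        denom = vx * vx + vy * vy
        if denom == 0:
            dist = np.hypot(px - x0, py - y0)
        else:
            s = np.clip(((px - x0) * vx + (py - y0) * vy) / denom, 0.0, 1.0)
            dist = np.hypot(px - (x0 + s * vx), py - (y0 + s * vy))
        cover = np.clip(w_px / 2 + 0.5 - dist, 0.0, 1.0)   # anti-aliased capsule
        np.maximum(img[rlo:rhi, clo:chi], rc.amplitude * cover,
                   out=img[rlo:rhi, clo:chi])

    if rc.psf_sigma_px > 0:
        img = gaussian_filter(img, rc.psf_sigma_px)
    img = img + rc.background
    if rc.poisson_noise or rc.read_noise_sd > 0:
        rng = np.random.default_rng(seed)
        if rc.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if rc.read_noise_sd > 0:
            img = img + rng.normal(0.0, rc.read_noise_sd, img.shape)
    maxval = 2 ** rc.bit_depth - 1
    out = np.clip(np.rint(img), 0, maxval).astype(_dtype(rc))
    return out, fs.to_frame().assign(cell_id=fs.cell_id or "")
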