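"""Display methods for orientation maps.

Two styles: a dipole map (oriented line segments on a gray background,
length proportional to peak intensity, color encoding tilt) and colormap
images (circular HSV hue for the in-plane angle, sequential jet for tilt,
brightness scaled to peak intensity between percentile bounds).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.draw import line as draw_line

from .orientation import OrientationMap

logger = logging.getLogger(__name__)

__all__ = ["RenderSpec", "render_colormap", "render_dipole_map", "brightness_channel"]

_STYLES = ("dipole", "colormap-phi", "colormap-theta")


@dataclass(frozen=True)
class RenderSpec:
    """Rendering options shared by both display styles."""

    style: str = "colormap-phi"
    mask_quantile: float = 60.0
    brightness_bounds: tuple = (35.0, 99.0)
    dipole_stride: int = 2
    wheel_rotation_deg: float = 0.0
    background_gray: float = 0.5

    def __post_init__(self):
        if self.style not in _STYLES:
            raise ValueError(f"style must be one of {_STYLES}, got {self.style!r}")
        lo, hi = self.brightness_bounds
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"brightness bounds must satisfy 0 <= low < high <= 100, got {self.brightness_bounds}")


def brightness_channel(i_max: np.ndarray, bounds=(35.0, 99.0)) -> np.ndarray:
    """Peak intensity clipped to percentile bounds and scaled to [0, 1]."""
    lo, hi = np.percentile(i_max, bounds)
    if hi <= lo:
        # degenerate (constant) image: full brightness everywhere
        return np.ones_like(i_max, dtype=float)
    return np.clip((i_max - lo) / (hi - lo), 0.0, 1.0)


def render_colormap(omap: OrientationMap, spec: RenderSpec | None = None) -> np.ndarray:
    """Colormap display: hue from the angle, brightness from i_max.

    The phi hue is exactly 180-degree periodic (circular HSV wheel); theta
    uses the sequential jet scale over [0, 90].  Invalid pixels render
    black.  Returns an (H, W, 3) float RGB array in [0, 1].
    """
    if spec is None:
        spec = RenderSpec()
    value = brightness_channel(omap.i_max, spec.brightness_bounds)
    if spec.style == "colormap-theta":
        cmap = colormaps["jet"]
        frac = np.clip(np.nan_to_num(omap.theta) / 90.0, 0.0, 1.0)
    else:
        cmap = colormaps["hsv"]
        frac = np.mod(np.nan_to_num(omap.phi) + spec.wheel_rotation_deg, 180.0) / 180.0
    rgb = cmap(frac)[..., :3]
    rgb = rgb * value[..., None]
    rgb[~omap.valid] = 0.0
    return rgb


def render_dipole_map(omap: OrientationMap, spec: RenderSpec | None = None) -> np.ndarray:
    """Dipole display: one oriented segment per supra-threshold pixel.

    Segment orientation encodes phi, length is proportional to i_max
    (capped at twice the stride), and color encodes theta on the jet scale.
    Returns an (H, W, 3) float RGB array on a gray background.
    """
    if spec is None:
        spec = RenderSpec(style="dipole")
    h, w = omap.shape
    canvas = np.full((h, w, 3), spec.background_gray, dtype=float)
    threshold = np.percentile(omap.i_max, spec.mask_quantile)
    show = omap.valid & (omap.i_max >= threshold)
    if not show.any():
        warnings.warn("all pixels masked; dipole render is empty")
        return canvas
    cmap = colormaps["jet"]
    stride = max(int(spec.dipole_stride), 1)
    max_len = 2.0 * stride
    i_ref = float(np.percentile(omap.i_max[show], 99.0))
    rows, cols = np.nonzero(show)
    keep = (rows % stride == 0) & (cols % stride == 0)
    for r, c in zip(rows[keep], cols[keep]):
        phi = omap.phi[r, c]
        half = 0.5 * max_len * min(omap.i_max[r, c] / i_ref, 1.0)
        dy = half * np.sin(np.radians(phi))
        dx = half * np.cos(np.radians(phi))
        r0, c0 = int(round(r - dy)), int(round(c - dx))
        r1, c1 = int(round(r + dy)), int(round(c + dx))
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        color = cmap(np.clip(omap.theta[r, c] / 90.0, 0.0, 1.0))[:3]
        canvas[rr[ok], cc[ok]] = color
    return canvas


def save_render(rgb: np.ndarray, path) -> None:
    """Write an RGB float array in [0, 1] as an 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8))
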