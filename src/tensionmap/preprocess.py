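"""Raw montage correction: baseline, illumination profile, phase averaging.

A raw acquisition is a stack of 3*P frames: three stripe orientations (one
per excitation polarization angle) times P phase shifts of the striped
illumination, P in {1, 3, 5}.  The correction recipe is:

1. subtract the camera baseline,
2. divide by a flat-field illumination profile built from uniform-sample
   acquisitions,
3. subtract the 1st percentile of the whole montage (skipped in timelapse
   mode, where frame-to-frame comparability matters more than offset),
4. clamp negative values to zero,
5. average the P phase frames of each orientation, which cancels the
   stripes exactly for phase steps of 2*pi/P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .orientation import AlphaTriplet, DEFAULT_ALPHAS, PolarizationTriplet

logger = logging.getLogger(__name__)

ORIENTATION_MAJOR = "orientation-major"
PHASE_MAJOR = "phase-major"


@dataclass
class SimMontage:
    """One raw acquisition: frames plus acquisition metadata.

    ``frames`` has shape (3*P, H, W).  With the default orientation-major
    layout, frames [0:P] share the first stripe orientation, [P:2P] the
    second, and so on; phase-major interleaves instead.
    """

    frames: np.ndarray
    alphas: AlphaTriplet = field(default_factory=lambda: AlphaTriplet(*DEFAULT_ALPHAS))
    camera_baseline: float = 200.0
    pixel_size_nm: float = 60.0
    layout: str = ORIENTATION_MAJOR
    timestamp_min: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be a (N, H, W) stack, got {self.frames.shape}")
        if self.frames.shape[0] % 3 != 0:
            raise ValueError(
                f"frame count must be divisible by 3, got {self.frames.shape[0]}"
            )
        if self.layout not in (ORIENTATION_MAJOR, PHASE_MAJOR):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0] // 3

    def frames_by_orientation(self) -> np.ndarray:
        """Frames reshaped to (3, P, H, W) regardless of layout."""
        p = self.n_phases
        h, w = self.frames.shape[1:]
        if self.layout == ORIENTATION_MAJOR:
            return self.frames.reshape(3, p, h, w)
        return self.frames.reshape(p, 3, h, w).transpose(1, 0, 2, 3)


@dataclass
class IlluminationProfile:
    """Flat-field correction montage, strictly positive, global mean ~ 1."""

    frames: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if np.any(self.frames <= 0):
            raise ValueError("illumination profile must be strictly positive")
        mean = float(self.frames.mean())
        if not np.isclose(mean, 1.0, rtol=1e-6):
            raise ValueError(f"illumination profile mean must be 1, got {mean}")


def _disk_kernel(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    kernel = (x * x + y * y <= radius * radius).astype(float)
    return kernel / kernel.sum()


def rolling_ball_smooth(image: np.ndarray, radius: int = 3) -> np.ndarray:
    """Grayscale smoothing with a disk kernel of the given pixel radius."""
    return ndimage.convolve(np.asarray(image, dtype=float), _disk_kernel(radius), mode="reflect")


def build_illumination_profile(
    montages,
    ball_radius: int = 3,
    min_montages: int = 6,
) -> IlluminationProfile:
    """Build a flat-field profile from uniform-sample acquisitions.

    Each montage is baseline-subtracted and smoothed frame-by-frame; the
    smoothed montages are averaged and the result normalized to a global
    mean of 1.

    Raises
    ------
    ValueError
        If no montages are given, shapes disagree, or the smoothed profile
        is not strictly positive.
    """
    montages = list(montages)
    if not montages:
        raise ValueError("at least one montage is required")
    if len(montages) < min_montages:
        logger.warning(
            "illumination profile built from %d montages (>= %d recommended)",
            len(montages),
            min_montages,
        )
    shape = montages[0].frames.shape
    acc = np.zeros(shape, dtype=float)
    for m in montages:
        if m.frames.shape != shape:
            raise ValueError("all montages must share one shape")
        sub = m.frames - m.camera_baseline
        acc += np.stack([rolling_ball_smooth(f, ball_radius) for f in sub])
    acc /= len(montages)
    mean = acc.mean()
    if mean <= 0 or np.any(acc <= 0):
        raise ValueError("smoothed illumination profile has nonpositive values")
    return IlluminationProfile(frames=acc / mean)


def correct_montage(
    montage: SimMontage,
    profile: IlluminationProfile | None = None,
    subtract_percentile: bool = True,
) -> SimMontage:
    """Apply the full correction recipe to a raw montage.

    Steps: baseline subtraction, flat-field division, montage-wide 1st
    percentile subtraction (disabled for timelapse mode), clamp to zero.
    Returns a new montage with baseline 0.
    """
    frames = montage.frames - montage.camera_baseline
    if profile is not None:
        if profile.frames.shape != frames.shape:
            raise ValueError(
                f"profile shape {profile.frames.shape} does not match montage {frames.shape}"
            )
        frames = frames / profile.frames
    if subtract_percentile:
        frames = frames - np.percentile(frames, 1.0)
    frames = np.clip(frames, 0.0, None)
    return replace(montage, frames=frames, camera_baseline=0.0)


def phase_average(montage: SimMontage) -> PolarizationTriplet:
    """Average the phase frames of each orientation into a triplet.

    For ideal sinusoidal stripes with phase steps of 2*pi/P the stripes
    cancel exactly, leaving the stripe-free mean illumination.
    """
    grouped = montage.frames_by_orientation()
    images = grouped.mean(axis=1)
    return PolarizationTriplet(
        images=images,
        alphas=montage.alphas,
        pixel_size_nm=montage.pixel_size_nm,
    )
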