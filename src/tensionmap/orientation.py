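"""Forward dipole-intensity model and the closed-form three-angle fit.

A pixel's fluorescence intensity under linearly polarized excitation at
in-plane angle ``alpha`` follows::

    I(alpha) = A * sin^2(alpha - phi) + c

where ``phi`` is the in-plane orientation of the force axis (axial, modulo
180 degrees) and the amplitude/offset pair (A, c) encodes the tilt angle
``theta`` of the force away from the optical axis:

    A = i_max * (1 - b) * sin^2(theta)
    c = i_max * (b + (1 - b) * cos^2(theta))

with ``i_max = A + c`` the peak of the sinusoid and ``b`` the fraction of
time the fluorophore spends unstacked (randomly oriented).

Three intensity samples at excitation angles spaced 60 degrees apart
determine (phi, A, c) uniquely.  The fit is implemented by second-harmonic
demodulation of the three samples, which is exact (zero residual) and free
of arctangent branch ambiguity: with doubled angles the three samples are
spaced 120 degrees, so the complex second-harmonic sum isolates
``A * exp(2j*phi)`` directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .circular import wrap_axial

logger = logging.getLogger(__name__)

#: Default unstacked-fluorophore fraction correction.
DEFAULT_B = 0.069

#: Excitation polarization triplet of the reference instrument (degrees).
DEFAULT_ALPHAS = (17.0, 77.0, 137.0)

#: Pixels with fractional amplitude A/i_max below this have no defined phi.
ORIENTATION_UNDEFINED_TOL = 1e-3


@dataclass(frozen=True)
class DipoleModelParams:
    """Parameters of the dipole intensity model.

    ``b`` corrects for the unstacked-fluorophore fraction; must lie in
    [0, 1).
    """

    b: float = DEFAULT_B

    def __post_init__(self):
        if not 0.0 <= self.b < 1.0:
            raise ValueError(f"b must be in [0, 1), got {self.b}")


@dataclass(frozen=True)
class AlphaTriplet:
    """Three excitation polarization angles, pairwise 60 degrees apart.

    Angles are reduced to [0, 180); the 60-degree spacing is checked
    modulo 180.
    """

    alpha1: float
    alpha2: float
    alpha3: float

    def __post_init__(self):
        object.__setattr__(self, "alpha1", float(self.alpha1) % 180.0)
        object.__setattr__(self, "alpha2", float(self.alpha2) % 180.0)
        object.__setattr__(self, "alpha3", float(self.alpha3) % 180.0)
        a = np.sort([self.alpha1, self.alpha2, self.alpha3])
        gaps = np.diff(np.concatenate([a, [a[0] + 180.0]]))
        if not np.allclose(gaps, 60.0, atol=1e-6):
            raise ValueError(
                f"alpha triplet must be spaced 60 degrees apart (mod 180), got {tuple(a)}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3], dtype=float)

    @classmethod
    def from_sequence(cls, alphas) -> "AlphaTriplet":
        a1, a2, a3 = alphas
        return cls(a1, a2, a3)


@dataclass(frozen=True)
class ForceOrientation:
    """In-plane angle ``phi`` (axial, [0, 180)) and tilt ``theta`` ([0, 90])."""

    phi: float
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "phi", float(self.phi) % 180.0)
        if not 0.0 <= self.theta <= 90.0:
            raise ValueError(f"theta must be in [0, 90], got {self.theta}")


@dataclass(frozen=True)
class SinusoidFit:
    """Result of the three-point sinusoid fit at one pixel.

    ``i_max = amplitude + offset`` always holds.  ``phi`` is nan when the
    orientation is undefined (constant input, amplitude ~ 0).  ``valid`` is
    False when the fit cannot support a tilt-angle computation (undefined
    orientation, nonpositive offset or peak).
    """

    amplitude: float
    offset: float
    phi: float
    orientation_defined: bool = True
    valid: bool = True

    @property
    def i_max(self) -> float:
        return self.amplitude + self.offset


def amplitude_offset(theta, i_max, b=DEFAULT_B):
    """Map tilt angle and peak intensity to the sinusoid pair (A, c)."""
    theta_r = np.radians(theta)
    i_max = np.asarray(i_max, dtype=float)
    a = i_max * (1.0 - b) * np.sin(theta_r) ** 2
    c = i_max * (b + (1.0 - b) * np.cos(theta_r) ** 2)
    return a, c


def forward_intensity(phi, theta, i_max, alpha, b=DEFAULT_B):
    """Expected intensity of a force dipole under polarized excitation.

    Total on the valid domain; periodic in ``alpha`` with period 180.
    Broadcasts over array inputs.
    """
    a, c = amplitude_offset(theta, i_max, b=b)
    return a * np.sin(np.radians(np.asarray(alpha, dtype=float) - phi)) ** 2 + c


def demodulate_triplet(intensities, alphas: AlphaTriplet):
    """Second-harmonic demodulation of three 60-degree-spaced samples.

    Parameters
    ----------
    intensities : array_like, shape (..., 3)
        Intensity samples ordered to match ``alphas``.
    alphas : AlphaTriplet
        Excitation angles of the three samples.

    Returns
    -------
    phi, amplitude, offset : ndarray
        Exact fit parameters; ``phi`` in [0, 180) (nan where the amplitude
        vanishes), ``amplitude >= 0`` by construction.
    """
    i = np.asarray(intensities, dtype=float)
    if i.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of length 3, got shape {i.shape}")
    alpha = np.radians(alphas.as_array())
    # I_k = (c + A/2) - (A/2) cos(2(alpha_k - phi)); the doubled angles are
    # 120 degrees apart, so sum_k I_k e^{2i alpha_k} = -(3A/4) e^{2i phi}.
    z = -(4.0 / 3.0) * np.sum(i * np.exp(2j * alpha), axis=-1)
    amplitude = np.abs(z)
    mean = np.mean(i, axis=-1)
    offset = mean - amplitude / 2.0
    with np.errstate(invalid="ignore"):
        phi = np.mod(np.degrees(np.angle(z)) / 2.0, 180.0)
    phi = np.where(amplitude > 0, phi, np.nan)
    return phi, amplitude, offset


def fit_three_point(
    i1,
    i2,
    i3,
    alphas: AlphaTriplet | None = None,
    undefined_tol: float = ORIENTATION_UNDEFINED_TOL,
) -> SinusoidFit:
    """Fit the intensity sinusoid exactly through three samples.

    Returns the unique (phi, A, c) with A >= 0 passing through the three
    points.  When the three samples are (nearly) equal the orientation is
    undefined: the fit is returned with A ~ 0 and ``orientation_defined``
    False.  A negative offset is permitted but flags the fit invalid for
    tilt-angle computation.
    """
    if alphas is None:
        alphas = AlphaTriplet(*DEFAULT_ALPHAS)
    vals = np.array([i1, i2, i3], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"intensities must be finite, got {vals}")
    phi, amplitude, offset = demodulate_triplet(vals, alphas)
    amplitude = float(amplitude)
    offset = float(offset)
    i_max = amplitude + offset
    scale = max(abs(i_max), 1e-300)
    defined = amplitude / scale >= undefined_tol and i_max > 0
    if not defined:
        return SinusoidFit(
            amplitude=amplitude,
            offset=offset,
            phi=float("nan"),
            orientation_defined=False,
            valid=False,
        )
    valid = offset > 0 and i_max > 0
    return SinusoidFit(
        amplitude=amplitude,
        offset=offset,
        phi=float(phi),
        orientation_defined=True,
        valid=valid,
    )


def theta_from_offset_fraction(offset, i_max, b=DEFAULT_B):
    """Vectorized tilt angle from the offset fraction ``c / i_max``.

    The argument of the square root is clipped to [0, 1]; the number of
    clipped entries is returned alongside the angles.
    """
    offset = np.asarray(offset, dtype=float)
    i_max = np.asarray(i_max, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (offset / i_max - b) / (1.0 - b)
    finite = np.isfinite(arg)
    n_clipped = int(np.count_nonzero(finite & ((arg < 0.0) | (arg > 1.0))))
    arg = np.clip(arg, 0.0, 1.0)
    theta = np.degrees(np.arccos(np.sqrt(arg)))
    return theta, n_clipped


def theta_from_fit(fit: SinusoidFit, params: DipoleModelParams | None = None) -> float:
    """Tilt angle in degrees from a sinusoid fit.

    Raises
    ------
    ValueError
        If the fit cannot support a tilt computation (invalid fit,
        nonpositive offset or peak intensity).
    """
    if params is None:
        params = DipoleModelParams()
    if not fit.valid or fit.offset <= 0 or fit.i_max <= 0:
        raise ValueError("tilt angle undefined: fit invalid or nonpositive offset/peak")
    theta, n_clipped = theta_from_offset_fraction(fit.offset, fit.i_max, b=params.b)
    if n_clipped:
        logger.debug("theta argument clipped to [0, 1] for scalar fit")
    return float(theta)


@dataclass
class PolarizationTriplet:
    """Three co-registered phase-averaged images tagged with alpha values."""

    images: np.ndarray  # shape (3, H, W)
    alphas: AlphaTriplet
    pixel_size_nm: float = 60.0

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != 3:
            raise ValueError(
                f"triplet images must have shape (3, H, W), got {self.images.shape}"
            )


@dataclass
class OrientationMap:
    """Per-pixel fit results over an image.

    All arrays share one 2-D shape.  ``phi``/``theta`` are nan on invalid
    pixels; ``valid`` combines the intensity mask with per-pixel fit
    validity.  ``n_theta_clipped`` counts pixels whose tilt-angle argument
    fell outside [0, 1] and was clipped.
    """

    phi: np.ndarray
    theta: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    i_max: np.ndarray
    valid: np.ndarray
    i_avg: np.ndarray | None = None
    alphas: AlphaTriplet | None = None
    b: float = DEFAULT_B
    mask_quantile: float = 60.0
    pixel_size_nm: float = 60.0
    n_theta_clipped: int = 0

    @property
    def shape(self):
        return self.phi.shape

    def to_table(self):
        """Per-pixel long-format table of the fit results."""
        import pandas as pd

        rows, cols = np.nonzero(np.ones(self.shape, dtype=bool))
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "phi_deg": self.phi.ravel(),
                "theta_deg": self.theta.ravel(),
                "amplitude": self.amplitude.ravel(),
                "offset": self.offset.ravel(),
                "i_max": self.i_max.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def fit_image_triplet(
    triplet: PolarizationTriplet,
    params: DipoleModelParams | None = None,
    mask_quantile: float = 60.0,
    undefined_tol: float = ORIENTATION_UNDEFINED_TOL,
) -> OrientationMap:
    """Per-pixel three-point fit over a polarization triplet.

    Pixels whose ``i_max`` does not exceed the ``mask_quantile``-th
    percentile of the image are marked invalid, as are pixels with an
    undefined orientation or nonpositive offset/peak.
    """
    if params is None:
        params = DipoleModelParams()
    imgs = triplet.images
    stacked = np.moveaxis(imgs, 0, -1)  # (H, W, 3)
    phi, amplitude, offset = demodulate_triplet(stacked, triplet.alphas)
    i_max = amplitude + offset
    i_avg = np.mean(imgs, axis=0)

    threshold = np.percentile(i_max, mask_quantile)
    supra = i_max >= threshold  # only pixels strictly below the threshold are masked
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(i_max > 0, amplitude / i_max, 0.0)
    defined = (frac >= undefined_tol) & (i_max > 0)
    computable = defined & (offset > 0)
    valid = supra & computable

    theta = np.full(i_max.shape, np.nan)
    theta_all, _ = theta_from_offset_fraction(offset, i_max, b=params.b)
    theta[computable] = theta_all[computable]
    # count clips only on pixels that survive masking
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (offset / i_max - params.b) / (1.0 - params.b)
    n_clipped = int(np.count_nonzero(valid & ((arg < 0.0) | (arg > 1.0))))
    if n_clipped:
        logger.info("theta argument clipped on %d valid pixels", n_clipped)
    phi = np.where(defined, phi, np.nan)
    phi_out = np.where(valid, phi, np.nan)
    theta_out = np.where(valid, theta, np.nan)

    return OrientationMap(
        phi=phi_out,
        theta=theta_out,
        amplitude=amplitude,
        offset=offset,
        i_max=i_max,
        valid=valid,
        i_avg=i_avg,
        alphas=triplet.alphas,
        b=params.b,
        mask_quantile=mask_quantile,
        pixel_size_nm=triplet.pixel_size_nm,
        n_theta_clipped=n_clipped,
    )


def polarization_response(
    omap: OrientationMap,
    cell_mask,
    background_mask,
    background_scale: float | None = None,
):
    """Polarization response ``<A> / (<c> + 1)`` over two regions.

    Means are taken over mask pixels of background-normalized amplitude and
    offset; ``background_scale`` divides both channels before averaging
    (default 1, i.e. inputs already normalized).  Returns the paired
    (cell, background) values for downstream rank-sum testing.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not cell_mask.any() or not background_mask.any():
        raise ValueError("polarization response requires nonempty masks")
    if np.any(cell_mask & background_mask):
        raise ValueError("cell and background masks must be disjoint")
    scale = 1.0 if background_scale is None else float(background_scale)
    if scale <= 0:
        raise ValueError("background_scale must be positive")

    def _metric(mask):
        a = np.mean(omap.amplitude[mask]) / scale
        c = np.mean(omap.offset[mask]) / scale
        return float(a / (c + 1.0))

    return _metric(cell_mask), _metric(background_mask)
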