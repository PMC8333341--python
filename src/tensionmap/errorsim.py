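"""Monte Carlo characterization of orientation-measurement error.

For a true orientation (phi, theta) at a photon budget i_max, the ideal
three-sample intensities are generated from the forward model, corrupted
with Poisson shot noise (plus optional Gaussian read noise), and refit with
the closed-form three-point fit.  Errors are summarized as

    eps_phi   = < |phi - phi*| >      (axial-wrapped absolute difference)
    sigma_phi = phi - <phi*>          (axial circular mean of phi*)
    eps_theta = < |theta - theta*| >
    sigma_theta = theta - <theta*>

where * marks measured values; eps is the random error, sigma the
systematic error.  phi differences are computed on doubled angles (axial
convention), so a phi error never exceeds 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .circular import axial_difference, axial_mean
from .orientation import (
    AlphaTriplet,
    DEFAULT_ALPHAS,
    DEFAULT_B,
    demodulate_triplet,
    forward_intensity,
    theta_from_offset_fraction,
)
from .synthetic import NoiseModel

__all__ = [
    "OrientationError",
    "ErrorSurface",
    "mc_orientation_error",
    "build_error_surface",
    "phi_uniformity_histogram",
]


class OrientationError(NamedTuple):
    eps_phi: float
    sigma_phi: float
    eps_theta: float
    sigma_theta: float


def _simulate_measurements(phi, theta, i_max, n_reps, alphas, b, noise, rng, frames_per_image=1):
    """Return (phi*, theta*) arrays over n_reps noisy refits.

    ``frames_per_image > 1`` emulates an acquisition whose three images are
    each the average of that many phase frames: shot noise is Poisson on
    the summed frame counts, reducing the per-image variance accordingly.
    """
    ideal = forward_intensity(phi, theta, i_max, alphas.as_array(), b=b)
    if noise.shot_noise:
        f = int(frames_per_image)
        samples = rng.poisson(np.broadcast_to(ideal * f, (n_reps, 3))).astype(float) / f
    else:
        samples = np.broadcast_to(ideal, (n_reps, 3)).copy()
    if noise.read_noise_sd > 0:
        samples = samples + rng.normal(0.0, noise.read_noise_sd, samples.shape)
    phi_m, amp, off = demodulate_triplet(samples, alphas)
    i_max_m = amp + off
    theta_m, _ = theta_from_offset_fraction(off, i_max_m, b=b)
    return phi_m, theta_m


def mc_orientation_error(
    phi: float,
    theta: float,
    i_max_photons: float,
    n_reps: int = 30000,
    noise: NoiseModel | None = None,
    seed: int = 0,
    alphas: AlphaTriplet | None = None,
    b: float = DEFAULT_B,
    frames_per_image: int = 1,
) -> OrientationError:
    """Random and systematic error of phi and theta at one true orientation.

    Deterministic given ``seed``.  Repetitions whose measured phi is
    undefined (zero amplitude, probability ~0 for i_max > 0) are excluded
    from the phi statistics.  ``frames_per_image`` emulates phase-averaged
    acquisition noise (see ``_simulate_measurements``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if i_max_photons <= 0:
        raise ValueError("i_max must be positive")
    if alphas is None:
        alphas = AlphaTriplet(*DEFAULT_ALPHAS)
    if noise is None:
        noise = NoiseModel(shot_noise=True, baseline=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    phi_m, theta_m = _simulate_measurements(
        phi, theta, i_max_photons, n_reps, alphas, b, noise, rng, frames_per_image
    )
    ok = np.isfinite(phi_m)
    eps_phi = float(np.mean(np.abs(axial_difference(phi_m[ok], phi))))
    sigma_phi = float(axial_difference(phi, axial_mean(phi_m[ok])))
    ok_t = np.isfinite(theta_m)
    eps_theta = float(np.mean(np.abs(theta_m[ok_t] - theta)))
    sigma_theta = float(theta - np.mean(theta_m[ok_t]))
    return OrientationError(eps_phi, sigma_phi, eps_theta, sigma_theta)


@dataclass
class ErrorSurface:
    """Error metrics over a (phi, theta) grid at fixed photon budget.

    Arrays are indexed [i_theta, i_phi].
    """

    phi_grid: np.ndarray
    theta_grid: np.ndarray
    eps_phi: np.ndarray
    sigma_phi: np.ndarray
    eps_theta: np.ndarray
    sigma_theta: np.ndarray
    i_max_photons: float
    n_reps: int
    seed: int

    def to_dataframe(self):
        import pandas as pd

        tt, pp = np.meshgrid(self.theta_grid, self.phi_grid, indexing="ij")
        return pd.DataFrame(
            {
                "phi_true": pp.ravel(),
                "theta_true": tt.ravel(),
                "eps_phi": self.eps_phi.ravel(),
                "sigma_phi": self.sigma_phi.ravel(),
                "eps_theta": self.eps_theta.ravel(),
                "sigma_theta": self.sigma_theta.ravel(),
            }
        )

    def phi_peak_to_peak(self):
        """Max-minus-min across phi of each metric, per theta row.

        Returns a dict of metric name -> array over theta_grid.
        """
        return {
            name: np.ptp(getattr(self, name), axis=1)
            for name in ("eps_phi", "sigma_phi", "eps_theta", "sigma_theta")
        }


def build_error_surface(
    i_max_photons: float,
    phi_grid=None,
    theta_grid=None,
    n_reps: int = 5000,
    seed: int = 0,
    noise: NoiseModel | None = None,
    alphas: AlphaTriplet | None = None,
    b: float = DEFAULT_B,
    frames_per_image: int = 1,
) -> ErrorSurface:
    """Evaluate the Monte Carlo error over an orientation grid."""
    if phi_grid is None:
        phi_grid = np.arange(0.0, 180.0, 15.0)
    if theta_grid is None:
        theta_grid = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
    phi_grid = np.asarray(phi_grid, dtype=float)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if phi_grid.size < 4 or theta_grid.size < 4:
        raise ValueError("grid resolution must be at least 4 per axis")
    shape = (theta_grid.size, phi_grid.size)
    out = {k: np.zeros(shape) for k in ("eps_phi", "sigma_phi", "eps_theta", "sigma_theta")}
    seeds = np.random.SeedSequence(seed).spawn(theta_grid.size * phi_grid.size)
    idx = 0
    for i, theta in enumerate(theta_grid):
        for j, phi in enumerate(phi_grid):
            cell_seed = seeds[idx].generate_state(1)[0]
            idx += 1
            err = mc_orientation_error(
                phi,
                theta,
                i_max_photons,
                n_reps=n_reps,
                noise=noise,
                seed=int(cell_seed),
                alphas=alphas,
                b=b,
                frames_per_image=frames_per_image,
            )
            for name, value in err._asdict().items():
                out[name][i, j] = value
    return ErrorSurface(
        phi_grid=phi_grid,
        theta_grid=theta_grid,
        i_max_photons=i_max_photons,
        n_reps=n_reps,
        seed=seed,
        **out,
    )


def phi_uniformity_histogram(
    n_pixels: int = 100000,
    i_max_photons: float = 1000.0,
    theta: float = 90.0,
    bins: int = 50,
    seed: int = 0,
    noise: NoiseModel | None = None,
    alphas: AlphaTriplet | None = None,
    b: float = DEFAULT_B,
    stratified: bool = False,
):
    """Histogram of recovered phi for a uniform true-phi population.

    Simulates ``n_pixels`` pixels with phi uniform on [0, 180) (stratified
    if requested) and theta fixed, recovers phi through the three-point
    fit, and bins the results into ``bins`` equal-width bins.

    Returns
    -------
    frequencies : ndarray, shape (bins,)
        Per-bin measurement frequency in percent (sums to 100).
    max_deviation : float
        Largest absolute deviation from the uniform ideal, in percent.
    """
    if n_pixels < bins:
        raise ValueError("need at least one pixel per bin")
    if alphas is None:
        alphas = AlphaTriplet(*DEFAULT_ALPHAS)
    if noise is None:
        noise = NoiseModel(shot_noise=True, baseline=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    if stratified:
        phi_true = (np.arange(n_pixels) + 0.5) * 180.0 / n_pixels
    else:
        phi_true = rng.uniform(0.0, 180.0, n_pixels)
    ideal = forward_intensity(
        phi_true[:, None], theta, i_max_photons, alphas.as_array()[None, :], b=b
    )
    if noise.shot_noise:
        samples = rng.poisson(ideal).astype(float)
    else:
        samples = ideal
    if noise.read_noise_sd > 0:
        samples = samples + rng.normal(0.0, noise.read_noise_sd, samples.shape)
    phi_m, _, _ = demodulate_triplet(samples, alphas)
    phi_m = phi_m[np.isfinite(phi_m)]
    counts, _ = np.histogram(phi_m, bins=bins, range=(0.0, 180.0))
    frequencies = 100.0 * counts / phi_m.size
    ideal_freq = 100.0 / bins
    return frequencies, float(np.max(np.abs(frequencies - ideal_freq)))
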