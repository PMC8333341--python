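"""Per-cell dynamics: drift/photobleach correction, tension area and
alignment time series, and their kinetic curve fits.

The tension-area trace T(t) of a spreading cell is modeled as a step onset
followed by saturating growth and a sigmoidal retraction back to baseline::

    T(t) = T_max * u(t - t_attach)
           * [ (1 - exp(-(t - t_attach)/tau_spread))
               - 1 / (1 + exp(-(t - t_attach - t_detach)/tau_retract)) ]
           + T0

and the alignment trace R(t) (when it trends) as a saturating exponential::

    R(t) = R_max - (R_max - R0) * exp(-(t - t_attach)/tau_align)

T(t) is fit by simulated annealing (exponential cooling, multiple restarts)
followed by local refinement; R(t) is fit with t_attach held fixed at the
value recovered from the T(t) fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.measure import profile_line
from skimage.registration import phase_cross_correlation

from .circular import alignment_parameter  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

__all__ = [
    "PlateletTrack",
    "SpreadFitParams",
    "AlignFitParams",
    "BleachFit",
    "spreading_model",
    "alignment_model",
    "drift_correct",
    "apply_shifts",
    "photobleach_correct",
    "tension_area",
    "alignment_parameter",
    "fit_spreading",
    "fit_alignment",
    "cohort_stats",
    "measure_edge_width",
]


# ---------------------------------------------------------------------------
# curve models


def spreading_model(t, t_max, t_attach, t_detach, tau_spread, tau_retract, t0):
    """Tension-area kinetic model; returns T(t) for array or scalar t."""
    t = np.asarray(t, dtype=float)
    dt = t - t_attach
    step = (dt >= 0).astype(float)
    with np.errstate(over="ignore"):
        grow = 1.0 - np.exp(-np.clip(dt, 0.0, None) / tau_spread)
        sigmoid = 1.0 / (1.0 + np.exp(-np.clip((dt - t_detach) / tau_retract, -500, 500)))
    return t_max * step * (grow - sigmoid) + t0


def alignment_model(t, r0, r_max, tau_align, t_attach):
    """Alignment kinetic model; exponential approach from r0 to r_max."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t_attach, 0.0, None)
    return r_max - (r_max - r0) * np.exp(-dt / tau_align)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class PlateletTrack:
    """Time series of tension area and alignment for one cell."""

    times_min: np.ndarray
    tension_area_um2: np.ndarray
    alignment: np.ndarray | None = None
    roi: tuple | None = None

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.tension_area_um2 = np.asarray(self.tension_area_um2, dtype=float)
        if self.times_min.shape != self.tension_area_um2.shape:
            raise ValueError("times and tension areas must have matching shape")
        if self.alignment is not None:
            self.alignment = np.asarray(self.alignment, dtype=float)
            if self.alignment.shape != self.times_min.shape:
                raise ValueError("alignment trace must match the time axis")
        steps = np.diff(self.times_min)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("time axis must be uniformly sampled")


@dataclass
class SpreadFitParams:
    """Best-fit parameters of the tension-area model."""

    t_max: float
    t_attach: float
    t_detach: float
    tau_spread: float
    tau_retract: float
    t0: float
    sse: float = np.nan
    rmse: float = np.nan
    flagged: bool = False
    message: str = ""

    def as_array(self):
        return np.array(
            [self.t_max, self.t_attach, self.t_detach, self.tau_spread, self.tau_retract, self.t0]
        )


@dataclass
class AlignFitParams:
    """Best-fit parameters of the alignment model plus trend class."""

    r0: float
    r_max: float
    tau_align: float
    trend: str  # "increasing" | "decreasing" | "none"
    p_value: float = np.nan

    @property
    def delta_r(self) -> float:
        return self.r_max - self.r0


@dataclass
class BleachFit:
    """Exponential background-decay fit ``a * exp(-t / tau)``."""

    amplitude: float
    tau_min: float
    corrected: bool = True


# ---------------------------------------------------------------------------
# stack corrections


def drift_correct(frames, upsample_factor: int = 50):
    """Estimate and remove cumulative translation drift from a stack.

    Translation between successive frames is measured by upsampled
    cross-correlation (after mean subtraction and Tukey edge tapering,
    which suppresses the FFT wraparound bias on non-periodic content) and
    accumulated; each frame is shifted back by its cumulative drift.  Flat
    (featureless) frames yield a zero shift with a warning.

    Returns
    -------
    corrected : ndarray, same shape as ``frames``
    shifts : ndarray, shape (T, 2)
        Cumulative (row, col) drift of each frame relative to the first.
    """
    from scipy.signal.windows import tukey

    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"expected a (T, H, W) stack, got shape {frames.shape}")
    n = frames.shape[0]
    shifts = np.zeros((n, 2))
    if n == 1:
        return frames.copy(), shifts
    taper = np.outer(tukey(frames.shape[1], 0.5), tukey(frames.shape[2], 0.5))

    def _prep(f):
        return (f - f.mean()) * taper

    def _flat(f):
        return f.std() <= 1e-9 * (abs(f.mean()) + 1.0)

    # each new frame is first pre-aligned with the running drift estimate so
    # that only the small per-frame residual is registered; this keeps the
    # content centered under the taper and avoids error accumulation
    reference = frames[0]
    for k in range(1, n):
        if _flat(reference) or _flat(frames[k]):
            warnings.warn("flat frame encountered during drift correction; assuming zero shift")
            shifts[k] = shifts[k - 1]
            reference = frames[k]
            continue
        pre_aligned = ndimage.shift(frames[k], -shifts[k - 1], order=1, mode="nearest")
        residual, _, _ = phase_cross_correlation(
            _prep(reference),
            _prep(pre_aligned),
            upsample_factor=upsample_factor,
            normalization=None,
        )
        # phase_cross_correlation returns the shift registering the moving
        # image onto the reference; its content is displaced by -residual
        shifts[k] = shifts[k - 1] - np.asarray(residual, dtype=float)
        reference = ndimage.shift(frames[k], -shifts[k], order=1, mode="nearest")
    corrected = np.stack(
        [ndimage.shift(frames[k], -shifts[k], order=1, mode="nearest") for k in range(n)]
    )
    return corrected, shifts


def apply_shifts(frames, shifts):
    """Shift every frame of a stack by the negated cumulative drift."""
    frames = np.asarray(frames, dtype=float)
    return np.stack(
        [ndimage.shift(f, -np.asarray(s, dtype=float), order=1, mode="nearest") for f, s in zip(frames, shifts)]
    )


def photobleach_correct(frames, background_mask, times_min, fit_offset: bool = False):
    """Normalize a stack by an exponential fit to its background decay.

    The mean background intensity per frame is fit to ``a * exp(-t/tau)``
    (plus an optional offset) and the stack divided by the fitted curve
    normalized to t = 0.  A non-decaying background disables the correction
    with a warning (tau = inf).
    """
    frames = np.asarray(frames, dtype=float)
    times = np.asarray(times_min, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    if not mask.any():
        raise ValueError("background mask is empty")
    bg = np.array([f[mask].mean() for f in frames])
    if bg[-1] >= bg[0] or bg[0] <= 0:
        warnings.warn("background is not decaying; photobleach correction disabled")
        return frames.copy(), BleachFit(amplitude=float(bg[0]), tau_min=np.inf, corrected=False)
    t_rel = times - times[0]
    span = max(t_rel[-1], 1.0)
    try:
        if fit_offset:
            popt, _ = optimize.curve_fit(
                lambda t, a, tau, off: a * np.exp(-t / tau) + off,
                t_rel,
                bg,
                p0=(bg[0] - bg[-1], span / 2.0, bg[-1]),
                maxfev=10000,
            )
            a, tau, off = popt
            curve = a * np.exp(-t_rel / tau) + off
        else:
            popt, _ = optimize.curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau),
                t_rel,
                bg,
                p0=(bg[0], span / 2.0),
                maxfev=10000,
            )
            a, tau = popt
            curve = a * np.exp(-t_rel / tau)
    except RuntimeError:
        warnings.warn("photobleach fit failed to converge; correction disabled")
        return frames.copy(), BleachFit(amplitude=float(bg[0]), tau_min=np.inf, corrected=False)
    if tau <= 0:
        warnings.warn("photobleach fit gave nonpositive tau; correction disabled")
        return frames.copy(), BleachFit(amplitude=float(bg[0]), tau_min=np.inf, corrected=False)
    factor = curve / curve[0]
    corrected = frames / factor[:, None, None]
    return corrected, BleachFit(amplitude=float(a), tau_min=float(tau), corrected=True)


# ---------------------------------------------------------------------------
# scalar measurements


def tension_area(
    i_max_image,
    pixel_size_nm: float = 60.0,
    threshold: float | None = None,
    background_mask=None,
    k: float = 3.0,
) -> float:
    """Area (um^2) of supra-threshold tension signal.

    The threshold defaults to background mean + k * background sd when a
    background mask is given, otherwise to an explicit ``threshold``
    (required in that case unless the image is empty).
    """
    img = np.asarray(i_max_image, dtype=float)
    if threshold is None:
        if background_mask is not None:
            bg = img[np.asarray(background_mask, dtype=bool)]
            if bg.size == 0:
                raise ValueError("background mask is empty")
            threshold = float(bg.mean() + k * bg.std())
        else:
            threshold = 0.0
    n = int(np.count_nonzero(img > threshold))
    px_um2 = (pixel_size_nm * 1e-3) ** 2
    return n * px_um2


# ---------------------------------------------------------------------------
# simulated annealing fit of the spreading model


def _spread_sse(params, t, y):
    resid = spreading_model(t, *params) - y
    return float(resid @ resid)


def _anneal(objective, x0, bounds, rng, n_iter=1500, t_frac_final=1e-4):
    lo = bounds[:, 0]
    hi = bounds[:, 1]
    span = hi - lo
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = objective(x)
    best_x, best_f = x.copy(), fx
    temp0 = max(fx, 1e-12)
    for i in range(n_iter):
        frac = i / max(n_iter - 1, 1)
        temp = temp0 * t_frac_final**frac  # exponential cooling
        sigma = span * (0.25 * (1.0 - frac) + 0.01)
        j = rng.integers(len(x))
        cand = x.copy()
        cand[j] = np.clip(x[j] + rng.normal(0.0, sigma[j]), lo[j], hi[j])
        fc = objective(cand)
        if fc < fx or rng.random() < np.exp(-(fc - fx) / max(temp, 1e-300)):
            x, fx = cand, fc
            if fx < best_f:
                best_x, best_f = x.copy(), fx
    return best_x, best_f


def fit_spreading(
    track: PlateletTrack,
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 1500,
    rmse_flag_fraction: float = 0.25,
) -> SpreadFitParams:
    """Fit the tension-area model to a track by simulated annealing.

    Exponential-cooling annealing with ``n_restarts`` independent restarts
    (heuristic initial guess plus random draws within bounds), refined by a
    bounded Powell local search.  Deterministic given ``seed``.

    Tracks with a near-zero amplitude or a residual RMSE above
    ``rmse_flag_fraction * T_max`` are flagged rather than rejected.
    """
    t = track.times_min
    y = track.tension_area_um2
    if t.size < 10:
        raise ValueError("spreading fit requires at least 10 timepoints")
    rng = np.random.default_rng(seed)
    y_max = float(y.max())
    y_min = float(y.min())
    span_t = float(t[-1] - t[0])
    dt = float(t[1] - t[0])
    eps = max(y_max, 1.0) * 1e-6
    bounds = np.array(
        [
            (0.0, 2.0 * max(y_max, eps)),  # T_max
            (t[0] - dt, t[-1]),  # t_attach
            (dt / 2.0, 2.0 * span_t),  # t_detach
            (0.1, 60.0),  # tau_spread
            (0.1, 60.0),  # tau_retract
            (0.0, max(y_max, eps)),  # T0
        ]
    )

    # heuristic initial guess from the trace shape
    amp = y_max - y_min
    if amp > 0:
        above = np.nonzero(y > y_min + 0.2 * amp)[0]
        t_attach0 = t[max(above[0] - 1, 0)] if above.size else t[0]
        high = np.nonzero(y > y_min + 0.5 * amp)[0]
        t_detach0 = max(t[high[-1]] - t_attach0, dt) if high.size else span_t / 2.0
    else:
        t_attach0, t_detach0 = t[0], span_t / 2.0
    x0 = np.array([amp if amp > 0 else eps, t_attach0, t_detach0, 2.0, 5.0, y_min])

    objective = lambda p: _spread_sse(p, t, y)
    best_x, best_f = None, np.inf
    for r in range(n_restarts):
        if r == 0:
            start = x0
        else:
            start = bounds[:, 0] + rng.random(6) * (bounds[:, 1] - bounds[:, 0])
        xr, fr = _anneal(objective, start, bounds, rng, n_iter=n_iter)
        if fr < best_f:
            best_x, best_f = xr, fr

    res = optimize.minimize(
        objective,
        best_x,
        method="Powell",
        bounds=[tuple(b) for b in bounds],
        options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
    )
    x = res.x if res.fun <= best_f else best_x
    sse = float(min(res.fun, best_f))
    rmse = float(np.sqrt(sse / t.size))
    flagged = False
    message = ""
    if x[0] <= 10.0 * eps:
        flagged, message = True, "degenerate: near-zero amplitude"
    elif x[0] > 0 and rmse > rmse_flag_fraction * x[0]:
        flagged, message = True, "poor fit: residual RMSE above threshold"
    return SpreadFitParams(
        t_max=float(x[0]),
        t_attach=float(x[1]),
        t_detach=float(x[2]),
        tau_spread=float(x[3]),
        tau_retract=float(x[4]),
        t0=float(x[5]),
        sse=sse,
        rmse=rmse,
        flagged=flagged,
        message=message,
    )


def fit_alignment(
    track: PlateletTrack,
    t_attach: float,
    t_detach: float,
    alpha: float = 0.05,
) -> AlignFitParams:
    """Fit the alignment model over the attach-to-detach window.

    ``t_attach`` is held fixed (taken from the tension-area fit).  The
    trend class is "none" when the rank correlation of (t, R) inside the
    window is not significant at level ``alpha``; otherwise the sign of the
    correlation gives "increasing" or "decreasing" and the exponential
    model is fit with R0, R_max and tau_align free.
    """
    if track.alignment is None:
        raise ValueError("track carries no alignment trace")
    t = track.times_min
    r = track.alignment
    window = (t >= t_attach) & (t <= t_attach + t_detach)
    tw, rw = t[window], r[window]
    if tw.size < 3:
        raise ValueError("alignment window shorter than 3 samples; unclassifiable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(tw, rw)
    if not np.isfinite(rho) or p >= alpha:
        return AlignFitParams(
            r0=float(rw[0]), r_max=float(rw[-1]), tau_align=np.nan, trend="none", p_value=float(p)
        )
    trend = "increasing" if rho > 0 else "decreasing"
    span = max(tw[-1] - tw[0], 1.0)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, r0, r_max, tau: alignment_model(tt, r0, r_max, tau, t_attach),
            tw,
            rw,
            p0=(float(np.clip(rw[0], 0, 1)), float(np.clip(rw[-1], 0, 1)), span / 4.0),
            bounds=([0.0, 0.0, 0.05], [1.0, 1.0, 120.0]),
            maxfev=10000,
        )
        r0, r_max, tau = (float(v) for v in popt)
    except RuntimeError:
        r0, r_max, tau = float(rw[0]), float(rw[-1]), np.nan
    return AlignFitParams(r0=r0, r_max=r_max, tau_align=tau, trend=trend, p_value=float(p))


# ---------------------------------------------------------------------------
# cohort statistics


def cohort_stats(
    param_table: pd.DataFrame,
    group_col: str = "group",
    n_boot: int = 1000,
    seed: int = 0,
):
    """Median/IQR summary and two-sided rank-sum tests across groups.

    Parameters
    ----------
    param_table : DataFrame
        One row per cell; a ``group_col`` column plus numeric fit-parameter
        columns.

    Returns
    -------
    summary : DataFrame
        Per (group, parameter): median, 25th/75th percentiles, and a
        bootstrap confidence interval of the median.
    pvalues : DataFrame
        Two-sided rank-sum p-value per parameter for each group pair.
    """
    groups = list(param_table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("cohort statistics require at least 2 groups")
    for g in groups:
        if (param_table[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    params = [c for c in param_table.columns if c != group_col and np.issubdtype(param_table[c].dtype, np.number)]
    rng = np.random.default_rng(seed)

    rows = []
    for g in groups:
        sub = param_table[param_table[group_col] == g]
        for p in params:
            vals = sub[p].dropna().to_numpy()
            if vals.size == 0:
                continue
            boot = np.median(
                rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
            )
            rows.append(
                {
                    group_col: g,
                    "parameter": p,
                    "n": vals.size,
                    "median": float(np.median(vals)),
                    "q1": float(np.percentile(vals, 25)),
                    "q3": float(np.percentile(vals, 75)),
                    "median_ci_low": float(np.percentile(boot, 2.5)),
                    "median_ci_high": float(np.percentile(boot, 97.5)),
                }
            )
    summary = pd.DataFrame(rows)

    prows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            for p in params:
                v1 = param_table.loc[param_table[group_col] == g1, p].dropna()
                v2 = param_table.loc[param_table[group_col] == g2, p].dropna()
                if len(v1) == 0 or len(v2) == 0:
                    continue
                stat, pval = stats.ranksums(v1, v2)
                prows.append(
                    {"group_a": g1, "group_b": g2, "parameter": p, "statistic": float(stat), "p_value": float(pval)}
                )
    pvalues = pd.DataFrame(prows)
    return summary, pvalues


# ---------------------------------------------------------------------------
# linescan edge width


def measure_edge_width(
    image,
    start,
    end,
    pixel_size_nm: float = 60.0,
    background: float | None = None,
    linewidth: int = 1,
) -> float:
    """Full width at half maximum (nm) of a ridge crossed by a linescan.

    The profile is background-subtracted and normalized to its peak; the
    width is measured between the interpolated half-maximum crossings on
    either side of the peak.

    Raises
    ------
    ValueError
        If no peak with two half-maximum crossings is found.
    """
    img = np.asarray(image, dtype=float)
    profile = profile_line(img, start, end, linewidth=linewidth, mode="reflect")
    bg = float(profile.min()) if background is None else float(background)
    prof = profile - bg
    peak = int(np.argmax(prof))
    peak_val = prof[peak]
    if peak_val <= 0 or np.allclose(prof, prof[0]):
        raise ValueError("no ridge peak found along linescan")
    half = peak_val / 2.0

    def _cross(idx_range, direction):
        prev = peak
        for idx in idx_range:
            if prof[idx] <= half:
                # linear interpolation between idx and the previous sample
                frac = (prof[prev] - half) / (prof[prev] - prof[idx])
                return prev + direction * frac
            prev = idx
        return None

    left = _cross(range(peak - 1, -1, -1), -1.0)
    right = _cross(range(peak + 1, prof.size), 1.0)
    if left is None or right is None:
        raise ValueError("ridge peak does not fall to half maximum within the linescan")
    return float((right - left) * pixel_size_nm)
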