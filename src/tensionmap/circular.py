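"""Circular statistics for axial (180-degree periodic) angle data.

In-plane orientation angles carry a two-fold degeneracy: an angle and the
same angle plus 180 degrees describe the same measurement.  All statistics
here therefore operate on doubled angles, following the standard axial-data
convention (Fisher, "Statistical Analysis of Circular Data", ch. 2).
Angles are in degrees throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_difference",
    "axial_mean",
    "mean_resultant_length",
    "alignment_parameter",
]


def wrap_axial(phi):
    """Wrap angles into the canonical axial range [0, 180)."""
    return np.mod(phi, 180.0)


def axial_difference(a, b):
    """Signed smallest axial difference ``a - b`` in (-90, 90].

    Computed modulo 180 so that e.g. 179 and 1 differ by 2, not 178.
    """
    return -(np.mod(-(np.asarray(a, dtype=float) - b) + 90.0, 180.0) - 90.0)


def axial_mean(phi, weights=None):
    """Mean orientation of axial data via the doubled-angle resultant.

    Returns the angle in [0, 180).  Undefined (returns nan) when the
    resultant vanishes, e.g. for perfectly isotropic input.
    """
    phi = np.asarray(phi, dtype=float)
    z = np.exp(2j * np.radians(phi))
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        resultant = np.sum(w * z) / np.sum(w)
    else:
        resultant = np.mean(z)
    if np.abs(resultant) < 1e-12:
        return float("nan")
    return float(np.mod(np.degrees(np.angle(resultant)) / 2.0, 180.0))


def mean_resultant_length(phi, weights=None):
    """Length of the mean resultant vector of the doubled angles, in [0, 1]."""
    phi = np.asarray(phi, dtype=float)
    z = np.exp(2j * np.radians(phi))
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        return float(np.abs(np.sum(w * z) / np.sum(w)))
    return float(np.abs(np.mean(z)))


def alignment_parameter(phi, weights=None):
    """Alignment of a set of axial angles: one minus the circular variance.

    Equal to the mean resultant length of the doubled angles; 1 when every
    angle lies on a single axis, 0 for an isotropic set.

    Raises
    ------
    ValueError
        If ``phi`` is empty.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("alignment parameter undefined for empty angle set")
    return mean_resultant_length(phi, weights=weights)
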