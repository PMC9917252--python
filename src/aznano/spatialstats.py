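"""Ripley H-function analysis of per-AZ point patterns.

For a pattern of n points in a region of area A the (uncorrected)
Ripley K estimator is

    K(r) = A * sum_{i != j} 1[d_ij <= r] / (n (n - 1))

and H(r) = sqrt(K(r)/pi) - r.  H is zero in expectation under
complete spatial randomness, positive when points cluster, and its
maximum over r roughly marks the radius of the clustered structures —
here the Brp subclusters inside an active zone.  No edge correction
is applied; the region area is by default the AZ's own alpha-shape
area, so the statistic is evaluated inside the cluster footprint.

Curves are evaluated on an integer-nm grid from 0 to 120 nm and
averaged across AZs unweighted (each AZ one vote).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["HCurve", "HSummary", "default_radii", "ripley_h", "average_h_curves", "h_maximum"]


def default_radii() -> np.ndarray:
    """Integer-nm evaluation grid, 0..120 inclusive."""
    return np.arange(0.0, 121.0)


@dataclass
class HCurve:
    """H(r) for one point pattern on a fixed radius grid (nm)."""

    radii: np.ndarray
    h_values: np.ndarray
    n_points: int
    region_area: float  # nm²


@dataclass
class HSummary:
    """Pointwise mean ± SD of H curves with the location of the mean maximum."""

    radii: np.ndarray
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    n_curves: int
    r_max: float | None
    h_max: float | None


def ripley_h(points, region_area: float, radii=None) -> HCurve:
    """Uncorrected Ripley H function of a point set.

    ``points`` are (n, 2) coordinates in nm, ``region_area`` the
    reference area in nm² (the AZ alpha-shape area in the pipeline).
    Coincident points (blinking duplicates) count toward K at every
    radius, as they are genuine localization pairs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n < 2:
        raise ValueError("H function undefined for fewer than 2 points")
    if region_area <= 0:
        raise ValueError("region_area must be positive")
    r = default_radii() if radii is None else np.asarray(radii, dtype=float)
    d = np.sort(pdist(pts))
    # ordered pairs with d <= r: 2 * count of unordered pairs
    pairs = 2.0 * np.searchsorted(d, r, side="right")
    k = region_area * pairs / (n * (n - 1.0))
    h = np.sqrt(k / np.pi) - r
    return HCurve(r, h, n, float(region_area))


def average_h_curves(curves) -> HSummary:
    """Unweighted pointwise mean ± SD across AZs; max taken on the mean."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    r0 = curves[0].radii
    for c in curves[1:]:
        if len(c.radii) != len(r0) or not np.allclose(c.radii, r0):
            raise ValueError("curves must share a common radius grid")
    stack = np.vstack([c.h_values for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    mx = h_maximum((r0, mean))
    r_max, h_max = mx if mx is not None else (None, None)
    return HSummary(r0, mean, sd, len(curves), r_max, h_max)


def h_maximum(curve):
    """Location of the H maximum over r in (0, 120].

    Accepts an :class:`HCurve`, an :class:`HSummary` (its mean curve)
    or a ``(radii, values)`` pair.  Returns ``(r_max, h_max)`` with
    ``r_max`` the smallest radius attaining the global maximum, or
    ``None`` when the maximum is not positive (no clustering signal).
    """
    if isinstance(curve, HSummary):
        r, h = curve.radii, curve.mean_curve
    elif isinstance(curve, HCurve):
        r, h = curve.radii, curve.h_values
    else:
        r, h = curve
        r = np.asarray(r, dtype=float)
        h = np.asarray(h, dtype=float)
    pos = r > 0
    r, h = r[pos], h[pos]
    if len(h) == 0:
        return None
    i = int(np.argmax(h))  # argmax returns the first index: smallest r
    if h[i] <= 0:
        return None
    return float(r[i]), float(h[i])
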