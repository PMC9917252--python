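"""Quality metrics: NeNA localization precision and mask-based SNR.

NeNA (nearest-neighbour based analysis) estimates the localization
precision sigma from re-localizations of the same molecule in
consecutive frames: for every localization in frame t the nearest
neighbour in frame t+1 is collected, and the distance histogram is
fitted with the same-molecule model

    p(d) = (d / (2 sigma²)) exp(-d² / (4 sigma²))

(the distance between two independent 2D Gaussian localizations of
one emitter, each with precision sigma) plus a linear term for
different-molecule pairs.  The fitted density peaks at sqrt(2)*sigma.

The signal-to-noise ratio divides the mean AZ localization density by
the extrasynaptic background density, where "extrasynaptic" is the
inverse of the 80-thresholded 8-bit epifluorescence bouton mask and
AZ signal has been cut out beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .azcluster import AZCluster
from .locio import EpiImage, LocalizationTable

__all__ = ["PrecisionEstimate", "SNRReport", "nena_precision", "snr", "same_molecule_density"]

NM2_PER_UM2 = 1e6


@dataclass
class PrecisionEstimate:
    sigma: float          # nm
    fit_range: float      # nm, histogram upper edge
    n_pairs: int


@dataclass
class SNRReport:
    az_density: float          # locs/µm², mean over kept AZs
    background_density: float  # locs/µm²
    snr: float

    def __post_init__(self):
        # invariant: the ratio is literally the quotient of the two
        assert np.isclose(self.snr, self.az_density / self.background_density)


def same_molecule_density(d, sigma):
    """Distance density for consecutive re-localizations of one emitter."""
    d = np.asarray(d, dtype=float)
    return d / (2.0 * sigma**2) * np.exp(-(d**2) / (4.0 * sigma**2))


def consecutive_frame_nn(locs: LocalizationTable) -> np.ndarray:
    """Nearest-neighbour distances from frame t to frame t+1."""
    order = np.argsort(locs.frame, kind="stable")
    frames = locs.frame[order]
    xy = locs.xy[order]
    bounds = np.searchsorted(frames, np.arange(frames.min(), frames.max() + 2))
    uniq = np.arange(frames.min(), frames.max() + 1)
    dists = []
    for i, t in enumerate(uniq[:-1]):
        a = xy[bounds[i]:bounds[i + 1]]
        b = xy[bounds[i + 1]:bounds[i + 2]]
        if len(a) == 0 or len(b) == 0:
            continue
        tree = cKDTree(b)
        d, _ = tree.query(a, k=1)
        dists.append(d)
    return np.concatenate(dists) if dists else np.empty(0)


def nena_precision(
    locs: LocalizationTable, fit_range: float = 100.0, min_pairs: int = 100
) -> PrecisionEstimate:
    """Estimate localization precision from consecutive-frame NN distances.

    Fits the same-molecule distance model plus a linear background to
    the 1-nm-binned distance histogram on [0, fit_range].  Raises
    ``ValueError`` when fewer than ``min_pairs`` pairs are available
    (use a larger input).
    """
    d = consecutive_frame_nn(locs)
    if d.size < min_pairs:
        raise ValueError(
            f"only {d.size} consecutive-frame NN pairs (< {min_pairs}); "
            "use a larger localization table"
        )
    d_in = d[d < fit_range]
    if d_in.size < min_pairs:
        raise ValueError("too few pairs inside the fit range")
    # same-molecule distances are Rayleigh with median 1.665*sigma;
    # distant different-molecule pairs must not steer the start value
    med = float(np.median(d_in))
    if med < 0.05:
        # exact re-localizations: precision indistinguishable from zero
        return PrecisionEstimate(max(med / 1.665, 1e-6), fit_range, int(d.size))

    edges = np.arange(0.0, fit_range + 1.0, 1.0)
    counts, _ = np.histogram(d_in, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / counts.sum()  # per-bin probability (bin width 1 nm)

    def model(d_, sigma, w):
        bg = 2.0 * d_ / fit_range**2
        return w * same_molecule_density(d_, sigma) + (1.0 - w) * bg

    sigma0 = min(max(med / 1.665, 0.5), 50.0)
    popt, _ = curve_fit(
        model, centers, dens, p0=[sigma0, 0.8],
        bounds=([1e-3, 0.0], [fit_range, 1.0]), maxfev=20000,
    )
    return PrecisionEstimate(float(popt[0]), fit_range, int(d.size))


def _pixel_lookup(grid: np.ndarray, locs: LocalizationTable, pixel_size: float):
    """Boolean grid value at each localization (False outside the grid)."""
    jx = np.floor(locs.x / pixel_size).astype(int)
    iy = np.floor(locs.y / pixel_size).astype(int)
    ny, nx = grid.shape
    inside = (jx >= 0) & (jx < nx) & (iy >= 0) & (iy < ny)
    out = np.zeros(len(locs), dtype=bool)
    out[inside] = grid[iy[inside], jx[inside]]
    return out


def snr(
    azs: list[AZCluster],
    locs: LocalizationTable,
    mask: EpiImage,
    threshold: int = 80,
) -> SNRReport:
    """Signal-to-noise ratio of one measurement.

    Signal: mean over kept AZs of n_locs/area.  Noise: localizations
    remaining after cutting the AZ signal that fall on inverse-mask
    pixels (pixel < threshold), divided by the inverse-mask area.
    Localizations outside the mask extent are ignored.

    Raises ``ValueError`` for an all-foreground mask or a zero
    background count (the ratio is undefined).
    """
    if not azs:
        raise ValueError("no kept AZs; SNR undefined")
    inv = mask.pixels < threshold
    n_inv = int(inv.sum())
    if n_inv == 0:
        raise ValueError("mask has no extrasynaptic (below-threshold) pixels")

    az_density = float(np.mean([az.density for az in azs]))

    # cut the AZ signal: members that lie inside the bouton mask plus
    # anything inside an AZ polygon.  Cluster members sitting on
    # extrasynaptic pixels stay — spatially they are background, and
    # the image-based cut this mirrors would never remove them.
    cut = np.zeros(len(locs), dtype=bool)
    fg_at = _pixel_lookup(mask.pixels >= threshold, locs, mask.pixel_size)
    for az in azs:
        cut[az.member_indices] = fg_at[az.member_indices]
        if az.polygon is not None and not getattr(az.polygon, "is_empty", True):
            from shapely import contains_xy
            inside_poly = contains_xy(az.polygon, locs.x, locs.y)
            cut |= inside_poly
    rest = locs.select(~cut)

    n_bg = int(_pixel_lookup(inv, rest, mask.pixel_size).sum())
    if n_bg == 0:
        raise ValueError("no background localizations; SNR undefined")
    inv_area_um2 = n_inv * mask.pixel_size**2 / NM2_PER_UM2
    bg_density = n_bg / inv_area_um2
    return SNRReport(az_density, bg_density, az_density / bg_density)
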