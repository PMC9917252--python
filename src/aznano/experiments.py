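"""Canned parameter-recovery experiments on synthetic data.

Each function generates data under fixed study conditions, runs the
corresponding analysis stage, and returns the recovered quantity.
They are the single source of the conditions used by the validation
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import quality, spatialstats
from .azcluster import AZCluster, SC_PARAMS_HPF, apply_az_filters, detect_az_clusters, detect_subclusters
from .geometry import alpha_shape_area
from .locio import LocalizationTable
from .synthgen import SyntheticParams, generate_az, generate_csr, generate_field

__all__ = [
    "h_maximum_recovery",
    "subcluster_count_recovery",
    "nena_recovery",
    "csr_h_null",
    "snr_recovery",
]


def h_maximum_recovery(
    preset: str, seed: int, n_az: int = 200, loc_sigma: float = 3.0
):
    """Averaged H-function maximum over synthetic AZs of one preset.

    AZs follow the preset geometry (13 uniform-disc subclusters of the
    preset radius, ~86 localizations each) with independent
    localizations jittered by ``loc_sigma``; per-AZ H curves use the
    AZ's own alpha-800 area and are averaged unweighted.

    Returns ``(r_max_nm, generative_sub_radius_nm)``.
    """
    maker = (SyntheticParams.paper_hpf if preset == "paper-hpf"
             else SyntheticParams.paper_pfa)
    params = maker(seed=seed, loc_sigma=loc_sigma, blink_mean=1.0)
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_az):
        table, _ = generate_az(params, rng)
        area = alpha_shape_area(table.xy, 800.0, with_boundary=False).area
        curves.append(spatialstats.ripley_h(table.xy, area))
    summary = spatialstats.average_h_curves(curves)
    return summary.r_max, params.sub_radius


def subcluster_count_recovery(seed: int, n_az: int = 50):
    """Median detected subcluster count on AZs generated with 13 SCs.

    Well-separated discs (edge gap ~11 nm), minimal unclustered
    background, jitter sigma 3 nm; detection with the HPF/FS
    parameters (20, 5).  Returns the median count across AZs.
    """
    params = SyntheticParams.paper_hpf(
        seed=seed, loc_sigma=3.0, blink_mean=1.0,
        az_noise_frac=0.05, sub_separation_factor=2.5,
    )
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_az):
        table, _ = generate_az(params, rng)
        az = AZCluster(0, np.arange(len(table)))
        counts.append(len(detect_subclusters(az, table, SC_PARAMS_HPF)))
    return float(np.median(counts))


def nena_recovery(seed: int, sigma: float = 6.7, n_emitters: int = 5000):
    """NeNA estimate for emitters re-localized over consecutive frames.

    Each emitter appears in 2-4 consecutive frames with isotropic
    Gaussian error ``sigma``; yields well over 5000 consecutive-frame
    nearest-neighbour pairs.  Returns the fitted sigma in nm.
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 20000.0, (n_emitters, 2))
    k = rng.integers(2, 5, n_emitters)
    xy, fr = [], []
    for i in range(n_emitters):
        start = rng.integers(0, 15000 - 4)
        xy.append(np.tile(pos[i], (k[i], 1)) + rng.normal(0, sigma, (k[i], 2)))
        fr.append(np.arange(start, start + k[i]))
    stacked = np.vstack(xy)
    table = LocalizationTable(stacked[:, 0], stacked[:, 1], np.concatenate(fr), None)
    return quality.nena_precision(table).sigma


def csr_h_null(seed: int, n_seeds: int = 100, density: float = 60.0, side: float = 5774.0):
    """Mean H curve of Poisson patterns (expected identically zero).

    ~2000 points per pattern; returns ``(radii, mean_curve)``.
    """
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_seeds):
        table = generate_csr(density, (0, 0, side, side), rng)
        curves.append(spatialstats.ripley_h(table.xy, side * side))
    summary = spatialstats.average_h_curves(curves)
    return summary.radii, summary.mean_curve


def snr_recovery(seed: int, n_fields: int = 20):
    """SNR on densely sampled synthetic fields vs the generative ratio.

    Fields use az_noise_frac 0.45 so the alpha-shape footprint
    resolves the true AZ area (see the methods note for why the
    sparser preset biases the area down).  Returns the mean ratio of
    measured SNR to the generative density ratio across fields.
    """
    ratios = []
    for i in range(n_fields):
        params = SyntheticParams.paper_hpf(seed=seed + i, az_noise_frac=0.45)
        table, mask, truth = generate_field(params)
        kept, _ = apply_az_filters(detect_az_clusters(table))
        report = quality.snr(kept, table, mask)
        true_signal = (
            (truth.az_id >= 0).sum() / len(truth.az_centers) / truth.true_az_area_um2
        )
        ratios.append(report.snr / (true_signal / truth.background_density))
    return float(np.mean(ratios))
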