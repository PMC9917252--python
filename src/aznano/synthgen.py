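"""Synthetic dSTORM localization data with known ground truth.

The generator emulates the statistical structure of Bruchpilot
active-zone (AZ) localization data at the Drosophila larval NMJ:

* an AZ is a disc-shaped cluster of ~1100-1500 localizations built
  from ~13 subclusters, each a uniform disc of radius ~20-30 nm;
* a fraction of AZ localizations is unclustered, spread uniformly over
  the AZ footprint (visible as unassigned points in real data);
* emitters blink: one fluorophore yields a geometric number of
  localizations on consecutive frames, each re-localized with
  isotropic Gaussian error sigma (this is what nearest-neighbour
  precision estimation keys on);
* boutons are ellipses; a homogeneous Poisson background covers the
  whole field; the epifluorescence mask is bright inside boutons.

Subclusters are uniform discs rather than Gaussians so that the
Ripley H-function maximum relates to a well-defined generative radius.
All randomness flows through one explicit numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .locio import EpiImage, LocalizationTable

__all__ = [
    "SyntheticParams",
    "SyntheticGroundTruth",
    "generate_az",
    "generate_field",
    "generate_csr",
]

NM2_PER_UM2 = 1e6


@dataclass
class SyntheticParams:
    """Generative parameters; defaults are the HPF/FS-like preset.

    AZ geometry: 13 uniform-disc subclusters (radius 22 nm, 86
    localizations each) in an AZ disc of radius 167 nm (area 0.088
    µm²), plus 25% unclustered AZ localizations; background 55
    localizations/µm²; localization error sigma 6.7 nm.  The PFA-like
    preset scales the AZ geometry by 28/22 and uses the classical-
    fixation background and precision.
    """

    seed: int
    n_az: int = 6
    az_radius: float = 167.0            # nm
    n_sub_per_az: int = 13
    sub_radius: float = 22.0            # nm
    locs_per_sub: int = 86
    az_noise_frac: float = 0.25         # unclustered fraction of AZ locs
    sub_separation_factor: float = 2.2  # min centre distance / sub_radius
    background_density: float = 55.0    # localizations / µm²
    loc_sigma: float = 6.7              # nm, isotropic localization error
    blink_mean: float = 2.0             # mean localizations per emitter
    frame_span: int = 15000
    field_size: tuple[float, float] = (12000.0, 8000.0)  # nm
    n_boutons: int = 3
    bouton_axes: tuple[float, float] = (1400.0, 950.0)   # ellipse semi-axes, nm
    az_min_separation_factor: float = 5.0  # min AZ centre distance / az_radius
    mask_pixel_size: float = 126.0
    mask_foreground: int = 200          # 8-bit value inside boutons

    def __post_init__(self) -> None:
        for name in ("az_radius", "sub_radius", "loc_sigma", "background_density",
                     "az_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.blink_mean < 1:
            raise ValueError("blink_mean must be >= 1")
        if not 0 <= self.az_noise_frac < 1:
            raise ValueError("az_noise_frac must be in [0, 1)")

    @classmethod
    def paper_hpf(cls, seed: int, **overrides) -> "SyntheticParams":
        """HPF/FS-like conditions (cryofixation)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def paper_pfa(cls, seed: int, **overrides) -> "SyntheticParams":
        """Classical-aldehyde-fixation-like conditions."""
        s = 28.0 / 22.0
        defaults = dict(
            az_radius=167.0 * s,
            sub_radius=28.0,
            background_density=74.0,
            loc_sigma=7.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class SyntheticGroundTruth:
    """True labels and generative geometry emitted next to the data.

    ``az_id``/``sub_id``/``emitter_id`` are per-localization; -1 means
    background (az_id), unclustered (sub_id) or background point
    (emitter_id).  The partition property: every localization has
    exactly one (az_id, sub_id) assignment.
    """

    az_id: np.ndarray
    sub_id: np.ndarray
    emitter_id: np.ndarray
    az_centers: np.ndarray          # (n_az, 2) nm
    az_radius: float
    sub_centers: dict               # az index -> (n_sub, 2) nm
    sub_radius: float
    background_density: float       # localizations / µm²
    params: SyntheticParams = None

    @property
    def true_az_area_um2(self) -> float:
        return np.pi * self.az_radius**2 / NM2_PER_UM2


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _uniform_disc(rng, n, radius, center=(0.0, 0.0)):
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(size=n))
    return np.asarray(center) + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _place_separated(rng, n, radius, min_sep, max_restarts=200, max_tries=2000):
    """n points in a disc of ``radius`` with pairwise distance >= min_sep."""
    for _ in range(max_restarts):
        pts: list[np.ndarray] = []
        for _ in range(n):
            for _ in range(max_tries):
                p = _uniform_disc(rng, 1, radius)[0]
                if all(np.hypot(*(p - q)) >= min_sep for q in pts):
                    pts.append(p)
                    break
            else:
                break
        if len(pts) == n:
            return np.array(pts)
    raise RuntimeError(
        f"could not place {n} points with separation {min_sep:.1f} nm "
        f"in a disc of radius {radius:.1f} nm"
    )


def _emitter_counts(rng, total, blink_mean):
    """Geometric per-emitter localization counts summing exactly to total."""
    if total == 0:
        return np.empty(0, dtype=int)
    if blink_mean <= 1.0:
        return np.ones(total, dtype=int)
    counts = []
    acc = 0
    p = 1.0 / blink_mean
    while acc < total:
        k = int(rng.geometric(p))
        k = min(k, total - acc)
        counts.append(k)
        acc += k
    return np.array(counts, dtype=int)


def _intensities(rng, n):
    # fitted spot amplitudes; all above the 12000 A/D analysis cutoff
    return 12001.0 + rng.exponential(8000.0, n)


def generate_az(
    params: SyntheticParams,
    rng=None,
    center=(0.0, 0.0),
    emitter_id_offset: int = 0,
):
    """Generate one active zone.

    Subcluster centres are placed in a disc of ``az_radius`` with
    minimum separation ``sub_separation_factor * sub_radius``; each
    subcluster emits exactly ``locs_per_sub`` localizations from
    blinking emitters positioned uniformly in a disc of ``sub_radius``;
    unclustered AZ localizations (fraction ``az_noise_frac`` of the AZ
    total) are uniform over the AZ disc.  Every localization is
    jittered by isotropic Gaussian noise of scale ``loc_sigma``, and
    one emitter's localizations occupy consecutive frames.

    Returns ``(LocalizationTable, SyntheticGroundTruth)``.
    """
    rng = _rng(params.seed if rng is None else rng)
    center = np.asarray(center, dtype=float)

    sub_centers = _place_separated(
        rng,
        params.n_sub_per_az,
        max(params.az_radius - params.sub_radius, 0.0),
        params.sub_separation_factor * params.sub_radius,
    ) + center

    xs, frames, sub_ids, emit_ids = [], [], [], []
    next_emitter = emitter_id_offset
    for s, c in enumerate(sub_centers):
        counts = _emitter_counts(rng, params.locs_per_sub, params.blink_mean)
        positions = _uniform_disc(rng, len(counts), params.sub_radius, c)
        for k, pos in zip(counts, positions):
            start = int(rng.integers(0, max(params.frame_span - k, 1)))
            xs.append(np.tile(pos, (k, 1)))
            frames.append(np.arange(start, start + k))
            sub_ids.append(np.full(k, s))
            emit_ids.append(np.full(k, next_emitter))
            next_emitter += 1

    n_clustered = params.n_sub_per_az * params.locs_per_sub
    nf = params.az_noise_frac
    n_noise = int(round(nf / (1.0 - nf) * n_clustered)) if nf > 0 else 0
    if n_noise:
        counts = _emitter_counts(rng, n_noise, params.blink_mean)
        positions = _uniform_disc(rng, len(counts), params.az_radius, center)
        for k, pos in zip(counts, positions):
            start = int(rng.integers(0, max(params.frame_span - k, 1)))
            xs.append(np.tile(pos, (k, 1)))
            frames.append(np.arange(start, start + k))
            sub_ids.append(np.full(k, -1))
            emit_ids.append(np.full(k, next_emitter))
            next_emitter += 1

    pts = np.vstack(xs)
    pts = pts + rng.normal(0.0, params.loc_sigma, pts.shape)
    frame = np.concatenate(frames)
    sub_id = np.concatenate(sub_ids)
    emitter_id = np.concatenate(emit_ids)

    table = LocalizationTable(
        pts[:, 0], pts[:, 1], frame, _intensities(rng, len(pts)), source_id="synthetic-az"
    )
    truth = SyntheticGroundTruth(
        az_id=np.zeros(len(pts), dtype=int),
        sub_id=sub_id,
        emitter_id=emitter_id,
        az_centers=center[None, :],
        az_radius=params.az_radius,
        sub_centers={0: sub_centers},
        sub_radius=params.sub_radius,
        background_density=0.0,
        params=params,
    )
    return table, truth


def generate_field(params: SyntheticParams, rng=None):
    """Generate a bouton chain: boutons, AZs inside them, background.

    Elliptical boutons are laid out as a chain across the field; AZ
    centres fall inside boutons with minimum pairwise separation
    ``az_min_separation_factor * az_radius``; a homogeneous Poisson
    background of ``background_density`` localizations/µm² covers the
    whole field.  The returned mask is bright (``mask_foreground``)
    inside boutons and 0 outside.

    Returns ``(LocalizationTable, EpiImage, SyntheticGroundTruth)``.
    """
    rng = _rng(params.seed if rng is None else rng)
    W, H = params.field_size
    a, b = params.bouton_axes

    # bouton chain: centres spread horizontally, jittered vertically
    n_b = params.n_boutons
    margin_x, margin_y = a * 1.05, b * 1.05
    if 2 * margin_x * n_b > W or 2 * margin_y > H:
        raise ValueError("boutons do not fit in the field")
    cx = np.linspace(margin_x, W - margin_x, n_b)
    cy = H / 2 + rng.uniform(-0.25, 0.25, n_b) * (H - 2 * margin_y) / 2
    bouton_centers = np.column_stack([cx, cy])

    def in_bouton(p):
        d = (p - bouton_centers) / (a, b)
        return (d**2).sum(axis=1) <= 1.0

    # AZ centres: inside some bouton (with az_radius margin), separated
    min_sep = params.az_min_separation_factor * params.az_radius
    az_centers: list[np.ndarray] = []
    tries = 0
    while len(az_centers) < params.n_az:
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place AZ centres; field too crowded")
        k = int(rng.integers(0, n_b))
        u = _uniform_disc(rng, 1, 1.0)[0]
        p = bouton_centers[k] + u * (
            a - params.az_radius, b - params.az_radius
        )
        if all(np.hypot(*(p - q)) >= min_sep for q in az_centers):
            az_centers.append(p)
    az_centers = np.array(az_centers) if az_centers else np.empty((0, 2))

    tables, az_ids, sub_ids, emit_ids, sub_centers = [], [], [], [], {}
    next_emitter = 0
    for i, c in enumerate(az_centers):
        t, g = generate_az(params, rng, center=c, emitter_id_offset=next_emitter)
        tables.append(t)
        az_ids.append(np.full(len(t), i))
        sub_ids.append(g.sub_id)
        emit_ids.append(g.emitter_id)
        sub_centers[i] = g.sub_centers[0]
        next_emitter = int(g.emitter_id.max()) + 1 if len(t) else next_emitter

    bg = generate_csr(params.background_density, (0.0, 0.0, W, H), rng)
    if len(bg):
        tables.append(bg)
        az_ids.append(np.full(len(bg), -1))
        sub_ids.append(np.full(len(bg), -1))
        emit_ids.append(np.full(len(bg), -1))

    if tables:
        x = np.concatenate([t.x for t in tables])
        y = np.concatenate([t.y for t in tables])
        frame = np.concatenate([t.frame for t in tables])
        inten = np.concatenate([t.intensity for t in tables])
        table = LocalizationTable(x, y, frame, inten, source_id="synthetic-field")
        az_id = np.concatenate(az_ids)
        sub_id = np.concatenate(sub_ids)
        emitter_id = np.concatenate(emit_ids)
    else:
        table = LocalizationTable.empty("synthetic-field")
        az_id = sub_id = emitter_id = np.empty(0, dtype=int)

    # 8-bit mask: bright inside any bouton ellipse
    psz = params.mask_pixel_size
    ny, nx = int(np.ceil(H / psz)), int(np.ceil(W / psz))
    yy, xx = np.mgrid[0:ny, 0:nx]
    px = (xx + 0.5) * psz
    py = (yy + 0.5) * psz
    inside = np.zeros((ny, nx), dtype=bool)
    for c in bouton_centers:
        inside |= ((px - c[0]) / a) ** 2 + ((py - c[1]) / b) ** 2 <= 1.0
    mask = EpiImage(
        np.where(inside, params.mask_foreground, 0).astype(np.uint8), psz
    )

    truth = SyntheticGroundTruth(
        az_id=az_id,
        sub_id=sub_id,
        emitter_id=emitter_id,
        az_centers=az_centers,
        az_radius=params.az_radius,
        sub_centers=sub_centers,
        sub_radius=params.sub_radius,
        background_density=params.background_density,
        params=params,
    )
    truth.bouton_centers = bouton_centers  # type: ignore[attr-defined]
    truth.bouton_axes = (a, b)             # type: ignore[attr-defined]
    return table, mask, truth


def generate_csr(density: float, region, rng=None, seed=None) -> LocalizationTable:
    """Homogeneous Poisson point process (complete spatial randomness).

    ``density`` is in localizations/µm²; ``region`` is
    ``(xmin, ymin, xmax, ymax)`` in nm.  The point count is
    Poisson(density x area) and positions are uniform.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = _rng(rng if rng is not None else seed)
    xmin, ymin, xmax, ymax = region
    area_um2 = (xmax - xmin) * (ymax - ymin) / NM2_PER_UM2
    n = int(rng.poisson(density * area_um2))
    if n == 0:
        return LocalizationTable.empty("csr")
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    frame = rng.integers(0, 15000, n)
    return LocalizationTable(x, y, frame, _intensities(rng, n), source_id="csr")


def write_ground_truth(truth: SyntheticGroundTruth, path) -> None:
    """Key-value sidecar with generative parameters and label arrays."""
    path = Path(path)
    lines = [
        f"az_radius_nm {truth.az_radius}",
        f"sub_radius_nm {truth.sub_radius}",
        f"background_density_per_um2 {truth.background_density}",
        f"n_az {len(truth.az_centers)}",
        "labels az_id sub_id emitter_id",
    ]
    for a, s, e in zip(truth.az_id, truth.sub_id, truth.emitter_id):
        lines.append(f"{a} {s} {e}")
    path.write_text("\n".join(lines) + "\n")
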