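"""End-to-end orchestration and group statistics.

Stage order is fixed: intensity-filtered read -> AZ clustering ->
alpha-shape areas -> exclusion filters -> subcluster detection ->
per-AZ H curves -> quality metrics (SNR when a mask is supplied,
NeNA) -> aggregation.  Every stage logs its input/output counts.

Group statistics follow standard practice for this kind of data:
Shapiro-Wilk normality check, then a two-tailed t-test for normal
data or a Mann-Whitney rank-sum test otherwise; for more than two
groups, Kruskal-Wallis one-way analysis on ranks with Dunn's multiple
comparisons versus a designated control.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import azcluster, quality, spatialstats
from .azcluster import ClusterParams, FilterThresholds
from .locio import EpiImage, LocalizationTable, read_localizations

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "GroupComparison",
    "run_pipeline",
    "compare_groups",
    "dunn_vs_control",
    "summarize_groups",
]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and input identifier."""

    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on '{source}': {cause}")
        self.stage = stage
        self.source = source
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through a flat TOML file.

    The two presets pin the published constants: A/D cutoff 12000,
    subcluster HDBSCAN parameters 24/6 (classical fixation,
    ``paper-pfa``) or 20/5 (cryofixation, ``paper-hpf``), alpha values
    800/300 nm², AZ exclusion bounds 0.03-0.3 µm² / 8000 localizations
    / 60000 locs/µm², mask threshold 80, radius grid 0-120 nm.
    """

    group: str = ""
    intensity_min: float = 12000.0
    az_min_cluster_size: int = 100
    az_min_samples: int = 20
    sc_min_cluster_size: int = 20
    sc_min_samples: int = 5
    alpha_az: float = 800.0   # nm²
    alpha_sc: float = 300.0   # nm²
    area_min: float = 0.03    # µm²
    area_max: float = 0.3     # µm²
    max_locs: int = 8000
    max_density: float = 60000.0
    mask_threshold: int = 80
    radius_max: float = 120.0  # nm, integer-step H grid upper end
    seed: int = 0

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name == "paper-hpf":
            base = dict(group="HPF-FS", sc_min_cluster_size=20, sc_min_samples=5)
        elif name == "paper-pfa":
            base = dict(group="PFA-RT", sc_min_cluster_size=24, sc_min_samples=6)
        else:
            raise ValueError(f"unknown preset: {name!r}")
        base.update(overrides)
        return cls(**base)

    # -- plain-text round trip ------------------------------------------
    def to_toml(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f'{f.name} = "{v}"' if isinstance(v, str) else f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    # -- views ----------------------------------------------------------
    @property
    def az_params(self) -> ClusterParams:
        return ClusterParams(self.az_min_cluster_size, self.az_min_samples, "AZ")

    @property
    def sc_params(self) -> ClusterParams:
        return ClusterParams(self.sc_min_cluster_size, self.sc_min_samples, "SC")

    @property
    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(self.area_min, self.area_max, self.max_locs, self.max_density)

    @property
    def radii(self) -> np.ndarray:
        return np.arange(0.0, self.radius_max + 1.0)


@dataclass
class PipelineResult:
    az_table: pd.DataFrame            # one row per detected AZ
    h_summary: spatialstats.HSummary | None
    h_curves: list                    # per-kept-AZ HCurve
    precision: quality.PrecisionEstimate | None
    snr_report: quality.SNRReport | None
    logs: list = field(default_factory=list)
    kept: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    subclusters: dict = field(default_factory=dict)  # az_id -> list[SubCluster]


def run_pipeline(
    config: PipelineConfig,
    locs,
    mask: EpiImage | None = None,
) -> PipelineResult:
    """Run the full analysis on one measurement.

    ``locs`` is a :class:`LocalizationTable` or a path to a
    localization file (read with the configured intensity cutoff).
    Supplying ``mask`` enables the SNR stage; everything else is
    unchanged without it.
    """
    logs: list[dict] = []
    source = getattr(locs, "source_id", str(locs))

    def stage(name, n_in, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineStageError(name, source, exc) from exc
        n_out = len(out) if hasattr(out, "__len__") else None
        logs.append({"stage": name, "n_in": n_in, "n_out": n_out})
        log.info("stage %-12s n_in=%s n_out=%s", name, n_in, n_out)
        return out

    if not isinstance(locs, LocalizationTable):
        locs = stage("read", None, lambda: read_localizations(locs, config.intensity_min))
        source = locs.source_id

    azs = stage(
        "az_cluster", len(locs),
        lambda: azcluster.detect_az_clusters(locs, config.az_params, config.alpha_az),
    )
    kept, excluded = stage(
        "az_filter", len(azs),
        lambda: azcluster.apply_az_filters(azs, config.thresholds),
    )
    logs[-1] = {"stage": "az_filter", "n_in": len(azs), "n_out": len(kept)}

    subclusters = stage(
        "subclusters", len(kept),
        lambda: {
            az.az_id: azcluster.detect_subclusters(az, locs, config.sc_params, config.alpha_sc)
            for az in kept
        },
    )

    def h_stage():
        curves = []
        for az in kept:
            if az.n_locs >= 2 and az.area > 0:
                curves.append(
                    spatialstats.ripley_h(locs.xy[az.member_indices], az.area * 1e6, config.radii)
                )
        return curves

    h_curves = stage("h_curves", len(kept), h_stage)
    h_summary = spatialstats.average_h_curves(h_curves) if h_curves else None

    precision = None
    try:
        precision = stage("nena", len(locs), lambda: quality.nena_precision(locs))
    except PipelineStageError as exc:
        if isinstance(exc.cause, ValueError):
            log.warning("NeNA skipped: %s", exc.cause)
        else:
            raise

    snr_report = None
    if mask is not None:
        snr_report = stage(
            "snr", len(kept),
            lambda: quality.snr(kept, locs, mask, config.mask_threshold),
        )

    rows = []
    for az in azs:
        is_kept = any(k.az_id == az.az_id for k in kept)
        reason = next((r for a, r in excluded if a.az_id == az.az_id), "")
        scs = subclusters.get(az.az_id, [])
        rows.append({
            "az_id": az.az_id,
            "n_locs": az.n_locs,
            "area_um2": az.area,
            "density_per_um2": az.density,
            "kept": is_kept,
            "exclude_reason": reason,
            "n_sc": len(scs) if is_kept else np.nan,
            "sc_area_median_nm2": float(np.median([s.area for s in scs])) if scs else np.nan,
        })
    az_table = pd.DataFrame(rows)

    return PipelineResult(
        az_table, h_summary, h_curves, precision, snr_report,
        logs, kept, excluded, subclusters,
    )


# ---------------------------------------------------------------------------
# group statistics

@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    normal: tuple[bool, ...] = ()
    posthoc: pd.DataFrame | None = None


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a normality-gated test choice.

    Shapiro-Wilk on each group; if both look normal at ``alpha``, a
    two-tailed t-test, otherwise the Mann-Whitney rank-sum test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    normal = tuple(
        bool(stats.shapiro(v).pvalue > alpha) if len(np.unique(v)) > 1 else False
        for v in (a, b)
    )
    if all(normal):
        res = stats.ttest_ind(a, b)
        return GroupComparison("t-test", float(res.statistic), float(res.pvalue), normal)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("rank-sum", float(res.statistic), float(res.pvalue), normal)


def dunn_vs_control(groups: dict, control: str) -> pd.DataFrame:
    """Dunn's multiple comparisons versus a control group.

    Pooled mean ranks with tie correction; z for each group against
    the control; p-values Bonferroni-adjusted over the number of
    comparisons (the form rank-based ANOVA post-hoc reports use).
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = np.array([len(v) for v in values])
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, n in zip(names, sizes):
        mean_ranks[g] = ranks[start:start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(names) - 1
    rows = []
    for g in names:
        if g == control:
            continue
        se = np.sqrt(var_base * (1.0 / len(groups[g]) + 1.0 / len(groups[control])))
        z = abs(mean_ranks[g] - mean_ranks[control]) / se
        p = min(1.0, k * 2.0 * stats.norm.sf(z))
        rows.append({"group": g, "control": control, "z": z, "p_adj": p})
    return pd.DataFrame(rows)


def compare_multi(groups: dict, control: str) -> GroupComparison:
    """Kruskal-Wallis across >2 groups plus Dunn's post-hoc vs control."""
    if len(groups) < 3:
        raise ValueError("use compare_groups for two groups")
    res = stats.kruskal(*[np.asarray(v, float) for v in groups.values()])
    posthoc = dunn_vs_control(groups, control)
    return GroupComparison(
        "kruskal+dunn", float(res.statistic), float(res.pvalue), posthoc=posthoc
    )


def summarize_groups(metrics: dict) -> pd.DataFrame:
    """Median (25th-75th percentile), mean ± SD and n per group metric.

    ``metrics`` maps (group, metric) or group -> vector.
    """
    rows = []
    for key, v in metrics.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        name = key if isinstance(key, str) else "/".join(map(str, key))
        rows.append({
            "group": name,
            "n": len(v),
            "median": np.median(v),
            "q25": np.percentile(v, 25),
            "q75": np.percentile(v, 75),
            "mean": v.mean(),
            "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
        })
    df = pd.DataFrame(rows)
    assert (df["q25"] <= df["median"]).all() and (df["median"] <= df["q75"]).all()
    return df
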