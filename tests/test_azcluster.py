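"""Two-level clustering and the AZ exclusion filters."""

import numpy as np
import pytest

from aznano.azcluster import (
    AZCluster,
    ClusterParams,
    FilterThresholds,
    SC_PARAMS_HPF,
    apply_az_filters,
    detect_az_clusters,
    detect_subclusters,
)
from aznano.locio import LocalizationTable
from aznano.synthgen import SyntheticParams, generate_az, generate_csr, generate_field


class TestDetectAZClusters:
    def test_recovers_well_separated_azs(self):
        table, mask, truth = generate_field(SyntheticParams.paper_hpf(seed=21, n_az=3))
        azs = detect_az_clusters(table)
        assert len(azs) == 3
        # membership: every ground-truth AZ fully recovered by one cluster
        for i in range(3):
            true_idx = set(np.flatnonzero(truth.az_id == i))
            best = max(azs, key=lambda a: len(true_idx & set(a.member_indices)))
            recall = len(true_idx & set(best.member_indices)) / len(true_idx)
            assert recall >= 0.99

    def test_csr_background_yields_no_clusters(self):
        """Pure Poisson background at 60/µm² over 100 µm² -> no AZs (majority of seeds)."""
        hits = 0
        for seed in range(20):
            t = generate_csr(60.0, (0, 0, 10000, 10000), seed=seed)
            hits += len(detect_az_clusters(t)) == 0
        assert hits >= 15

    def test_empty_and_tiny_tables(self):
        assert detect_az_clusters(LocalizationTable.empty()) == []
        tiny = LocalizationTable(np.arange(5.0), np.arange(5.0), None, None)
        assert detect_az_clusters(tiny) == []

    def test_permutation_invariance(self, hpf_field):
        """Shuffling rows preserves cluster composition (up to distance ties).

        Blinking duplicates create exactly tied mutual-reachability
        distances whose resolution is order-dependent in the HDBSCAN
        implementation, so a handful of boundary points may flip;
        cluster count and essentially all memberships must not.
        """
        table, _, _ = hpf_field
        azs = detect_az_clusters(table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        azs_shuffled = detect_az_clusters(table.select(perm))
        assert len(azs_shuffled) == len(azs)
        orig = [set(a.member_indices.tolist()) for a in azs]
        # map shuffled-row indices back to original rows
        back = [set(perm[a.member_indices].tolist()) for a in azs_shuffled]
        total = sum(len(s) for s in orig)
        matched = sum(max(len(s & t) for t in back) for s in orig)
        assert total - matched <= 5

    def test_areas_and_density_populated(self, hpf_field):
        table, _, _ = hpf_field
        for az in detect_az_clusters(table):
            assert az.area > 0
            assert az.density == pytest.approx(az.n_locs / az.area)
            assert az.polygon is not None


class TestDetectSubclusters:
    def test_single_tight_blob_is_one_subcluster(self, rng):
        pts = rng.normal(0, 10, (200, 2))
        t = LocalizationTable(pts[:, 0], pts[:, 1], None, None)
        az = AZCluster(0, np.arange(200))
        assert len(detect_subclusters(az, t, SC_PARAMS_HPF)) == 1

    def test_median_count_recovers_thirteen(self):
        """13 well-separated disc SCs, params (20, 5) -> median 13."""
        rng = np.random.default_rng(2)
        params = SyntheticParams.paper_hpf(
            seed=2, loc_sigma=3.0, blink_mean=1.0,
            az_noise_frac=0.05, sub_separation_factor=2.5,
        )
        counts = []
        for _ in range(25):
            t, _ = generate_az(params, rng)
            az = AZCluster(0, np.arange(len(t)))
            counts.append(len(detect_subclusters(az, t, SC_PARAMS_HPF)))
        assert np.median(counts) == 13

    def test_membership_agrees_with_ground_truth(self):
        rng = np.random.default_rng(4)
        params = SyntheticParams.paper_hpf(
            seed=4, loc_sigma=3.0, blink_mean=1.0,
            az_noise_frac=0.05, sub_separation_factor=2.5,
        )
        t, truth = generate_az(params, rng)
        az = AZCluster(0, np.arange(len(t)))
        scs = detect_subclusters(az, t, SC_PARAMS_HPF)
        # fraction of clustered ground-truth points assigned to a matching SC
        agree = total = 0
        for s in range(13):
            true_idx = set(np.flatnonzero(truth.sub_id == s))
            best = max(
                (len(true_idx & set(sc.member_indices)) for sc in scs), default=0
            )
            agree += best
            total += len(true_idx)
        assert agree / total >= 0.90

    def test_subclusters_restricted_to_az_members(self, hpf_az):
        table, _, _ = hpf_az
        members = np.arange(0, len(table), 2)
        az = AZCluster(0, members)
        for sc in detect_subclusters(az, table, SC_PARAMS_HPF):
            assert set(sc.member_indices) <= set(members)

    def test_small_az_gives_empty_list(self, hpf_az):
        table, _, _ = hpf_az
        az = AZCluster(0, np.arange(10))
        assert detect_subclusters(az, table, SC_PARAMS_HPF) == []


def _fake_az(az_id, area, n_locs):
    az = AZCluster(az_id, np.arange(n_locs))
    az.area = area
    return az


class TestFilters:
    def test_each_rule_and_oracle(self):
        """Crafted 8-AZ set, one violation per rule, checked brute-force."""
        azs = [
            _fake_az(0, 0.02, 1000),      # area below 0.03
            _fake_az(1, 0.35, 1000),      # area above 0.3
            _fake_az(2, 0.29, 8500),      # too many localizations
            _fake_az(3, 0.04, 3000),      # density 75000 > 60000
            _fake_az(4, 0.1, 1000),       # clean
            _fake_az(5, 0.25, 7000),      # clean
            _fake_az(6, 0.029, 100),      # area below 0.03 (boundary-ish)
            _fake_az(7, 0.05, 3200),      # density 64000 > 60000
        ]
        kept, excluded = apply_az_filters(azs)
        assert [a.az_id for a in kept] == [4, 5]
        reasons = {a.az_id: r for a, r in excluded}
        assert reasons == {
            0: "area_min", 1: "area_max", 2: "max_locs",
            3: "max_density", 6: "area_min", 7: "max_density",
        }
        # brute-force rule oracle: exclusion iff any strict violation
        thr = FilterThresholds()
        for az in azs:
            violates = (
                az.area < thr.area_min or az.area > thr.area_max
                or az.n_locs > thr.max_locs or az.density > thr.max_density
            )
            assert (az in kept) == (not violates)

    def test_boundary_values_kept(self):
        boundary = [
            _fake_az(0, 0.03, 1000),
            _fake_az(1, 0.3, 1000),
            _fake_az(2, 0.2, 8000),
            _fake_az(3, 0.1, 6000),  # density exactly 60000
        ]
        kept, excluded = apply_az_filters(boundary)
        assert len(kept) == 4 and excluded == []

    def test_partition(self, hpf_field):
        table, _, _ = hpf_field
        azs = detect_az_clusters(table)
        kept, excluded = apply_az_filters(azs)
        assert len(kept) + len(excluded) == len(azs)
        ids = {a.az_id for a in kept} | {a.az_id for a, _ in excluded}
        assert ids == {a.az_id for a in azs}

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            FilterThresholds(area_min=0.5, area_max=0.3)
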