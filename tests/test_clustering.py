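import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist

from lipodrop.clustering import (
    DEFAULT_THRESHOLD_PX,
    boundary_gap,
    cluster_size_stats,
    clusters_per_100_lds,
    find_clusters,
    size_histogram,
)
from lipodrop.io import DEFAULT_PIXEL_SIZE_UM
from lipodrop.segmentation import DropletRecord


def record_from_coords(rid, rows, cols, cell_id=1):
    img = np.ones((max(rows) + 2, max(cols) + 2))
    return DropletRecord.from_pixels(rid, np.asarray(rows), np.asarray(cols), img,
                                     DEFAULT_PIXEL_SIZE_UM, cell_id)


def disc_record(rid, center, radius, cell_id=1, grid=200):
    rr, cc = np.mgrid[:grid, :grid]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return DropletRecord.from_pixels(rid, *np.nonzero(m), np.ones((grid, grid)),
                                     DEFAULT_PIXEL_SIZE_UM, cell_id)


def oracle_partition(records, threshold):
    """Independent O(n^2) oracle: full-mask cdist + DFS transitive closure."""
    coords = {r.id: np.column_stack([r.rows, r.cols]) for r in records}
    by_cell = {}
    for r in records:
        by_cell.setdefault(r.cell_id, []).append(r.id)
    adj = {r.id: set() for r in records}
    for ids in by_cell.values():
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if cdist(coords[a], coords[b]).min() <= threshold:
                    adj[a].add(b)
                    adj[b].add(a)
    comps, seen = set(), set()
    for r in records:
        if r.id in seen:
            continue
        stack, comp = [r.id], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        if len(comp) >= 2:
            comps.add(frozenset(comp))
    return comps


class TestBoundaryGap:
    def test_identical_masks_zero(self):
        a = record_from_coords(1, [5, 5, 6], [5, 6, 5])
        b = record_from_coords(2, [5, 5, 6], [5, 6, 5])
        assert boundary_gap(a, b) == 0.0

    def test_four_adjacent_unit_gap(self):
        a = record_from_coords(1, [5], [5])
        b = record_from_coords(2, [5], [6])
        assert boundary_gap(a, b) == 1.0

    def test_pythagorean_offset(self):
        a = record_from_coords(1, [0], [0])
        b = record_from_coords(2, [3], [4])
        assert boundary_gap(a, b) == 5.0

    def test_symmetry(self):
        a = disc_record(1, (30, 30), 4)
        b = disc_record(2, (30, 44), 5)
        assert boundary_gap(a, b) == boundary_gap(b, a)

    def test_empty_mask_rejected(self):
        a = record_from_coords(1, [0], [0])
        a.rows = np.array([], dtype=int)
        with pytest.raises(ValueError):
            boundary_gap(a, a)


class TestFindClusters:
    def test_empty_input(self):
        assert find_clusters([]) == []

    def test_transitive_closure_chain(self):
        # A-B = 2.0, B-C = 2.0, A-C > threshold: one cluster {A, B, C}
        a = record_from_coords(1, [10], [10])
        b = record_from_coords(2, [10], [12])
        c = record_from_coords(3, [10], [14])
        clusters = find_clusters([a, b, c], threshold_px=2.0)
        assert len(clusters) == 1
        assert clusters[0].member_ids == frozenset({1, 2, 3})
        assert clusters[0].n_lds == 3

    def test_all_far_apart_no_clusters(self):
        recs = [record_from_coords(i, [10 * i], [10 * i]) for i in range(1, 5)]
        assert find_clusters(recs, 2.0) == []

    def test_clusters_never_span_cells(self):
        a = disc_record(1, (50, 50), 3, cell_id=1)
        b = disc_record(2, (50, 58), 3, cell_id=2)  # gap 2 but different cell
        assert find_clusters([a, b], 2.0) == []

    def test_unassigned_droplets_excluded(self):
        a = disc_record(1, (50, 50), 3, cell_id=None)
        b = disc_record(2, (50, 58), 3, cell_id=None)
        assert find_clusters([a, b], 2.0) == []

    def test_matches_brute_force_oracle_random(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 16))
            recs = []
            for i in range(1, n + 1):
                ctr = rng.uniform(10, 110, 2)
                recs.append(disc_record(i, ctr, rng.uniform(1.5, 4.0), cell_id=int(rng.integers(1, 3)), grid=130))
            got = {c.member_ids for c in find_clusters(recs, 2.0)}
            assert got == oracle_partition(recs, 2.0)

    def test_partition_and_threshold_monotonicity(self, rng):
        recs = [
            disc_record(i, rng.uniform(10, 150, 2), rng.uniform(1.5, 3.5), grid=170)
            for i in range(1, 21)
        ]
        lo = find_clusters(recs, 1.0)
        hi = find_clusters(recs, 4.0)
        # partition: no droplet in two clusters
        for cl_set in (lo, hi):
            all_ids = [m for c in cl_set for m in c.member_ids]
            assert len(all_ids) == len(set(all_ids))
        # raising the threshold merges, never splits
        for c in lo:
            assert any(c.member_ids <= h.member_ids for h in hi)
        n_groups_lo = len(lo) + (20 - sum(c.n_lds for c in lo))
        n_groups_hi = len(hi) + (20 - sum(c.n_lds for c in hi))
        assert n_groups_hi <= n_groups_lo


class TestClusterStats:
    def test_equal_areas_zero_sd(self):
        mean, sd = cluster_size_stats([1.0, 1.0])
        assert mean == 1.0 and sd == 0.0

    def test_closed_form_pair(self):
        mean, sd = cluster_size_stats([0.5, 1.5])
        assert mean == 1.0
        assert sd == pytest.approx(np.sqrt(2 * 0.25), abs=1e-12)

    def test_lognormal_matches_two_pass_oracle(self, rng):
        areas = rng.lognormal(-1.0, 0.8, size=1000)
        mean, sd = cluster_size_stats(areas)
        # independent two-pass computation
        m = sum(areas) / len(areas)
        s = np.sqrt(sum((a - m) ** 2 for a in areas) / (len(areas) - 1))
        assert mean == pytest.approx(m, rel=1e-12)
        assert sd == pytest.approx(s, rel=1e-12)

    def test_single_area_rejected(self):
        with pytest.raises(ValueError):
            cluster_size_stats([1.0])

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=30))
    def test_sd_nonnegative_and_mean_bounded(self, areas):
        mean, sd = cluster_size_stats(areas)
        assert sd >= 0
        assert min(areas) <= mean <= max(areas)


class TestRates:
    def test_ten_lds_two_clusters(self):
        recs = [disc_record(i, (20 + 12 * i, 20), 2) for i in range(1, 11)]
        clusters = [
            type("C", (), {"cell_id": 1, "n_lds": 2})(),
            type("C", (), {"cell_id": 1, "n_lds": 3})(),
        ]
        rates = clusters_per_100_lds(recs, clusters)
        assert rates[2] == 10.0 and rates[3] == 10.0
        assert rates[4] == rates[5] == rates["6+"] == 0.0

    def test_no_clusters_all_zero(self):
        recs = [disc_record(1, (20, 20), 2)]
        rates = clusters_per_100_lds(recs, [])
        assert all(v == 0.0 for v in rates.values())

    def test_zero_lds_missing(self):
        assert clusters_per_100_lds([], []) is None

    def test_weighted_sum_is_clustered_fraction(self, rng):
        for _ in range(30):
            recs = [
                disc_record(i, rng.uniform(10, 150, 2), rng.uniform(1.5, 3.0), grid=170)
                for i in range(1, int(rng.integers(3, 20)) + 1)
            ]
            clusters = find_clusters(recs, 2.0)
            rates = clusters_per_100_lds(recs, clusters)
            # sum_k k*rate_k/100 equals the clustered fraction (counting
            # oracle), using true cardinalities for the open 6+ bucket
            total = sum(k * rates[k] / 100.0 for k in (2, 3, 4, 5))
            total += sum(c.n_lds for c in clusters if c.n_lds >= 6) / len(recs)
            clustered_fraction = sum(c.n_lds for c in clusters) / len(recs)
            assert total == pytest.approx(clustered_fraction, abs=1e-9)
            assert total <= 1.0 + 1e-9


class TestSizeHistogram:
    def test_no_droplets(self):
        hist = size_histogram([])
        assert hist.loc["total"].sum() == 0

    def test_example_binning(self):
        recs = []
        for i, area in enumerate([0.3, 0.7, 1.7], start=1):
            r = disc_record(i, (20 * i, 20), 2)
            r.area_um2 = area
            recs.append(r)
        hist = size_histogram(recs)
        np.testing.assert_array_equal(hist.loc["total"].values, [1, 1, 0, 1, 0])

    def test_half_open_convention(self):
        r = disc_record(1, (20, 20), 2)
        r.area_um2 = 0.5
        hist = size_histogram([r])
        assert hist.loc["total", "[0.5,1)"] == 1
        assert hist.loc["total", "[0,0.5)"] == 0

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            size_histogram([], bin_edges_um2=[0.0, 1.0, 0.5])


class TestThresholdCalibration:
    def test_two_pixels_is_0266_um(self):
        assert DEFAULT_THRESHOLD_PX * DEFAULT_PIXEL_SIZE_UM == pytest.approx(0.266, abs=1e-12)
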