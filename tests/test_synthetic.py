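import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lipodrop.synthetic import (
    FieldSpec,
    PlacementError,
    _finish_channel,
    generate_field,
    generate_timelapse,
)


def brute_force_clusters(ld_labels: np.ndarray, cell_of: dict, threshold: float = 2.0):
    """Independent oracle: full pairwise mask-gap + transitive closure."""
    ids = sorted(int(i) for i in np.unique(ld_labels) if i > 0)
    coords = {i: np.column_stack(np.nonzero(ld_labels == i)) for i in ids}
    adj = {i: set() for i in ids}
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            if cell_of.get(a) != cell_of.get(b):
                continue
            if cdist(coords[a], coords[b]).min() <= threshold:
                adj[a].add(b)
                adj[b].add(a)
    seen, comps = set(), []
    for i in ids:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        if len(comp) >= 2:
            comps.append(frozenset(comp))
    return set(comps)


class TestGenerateField:
    def test_determinism_same_seed(self):
        spec = FieldSpec(seed=4, n_cells=1, width_px=384, height_px=384)
        img1, gt1 = generate_field(spec)
        img2, gt2 = generate_field(spec)
        for c in img1.channels:
            np.testing.assert_array_equal(img1.channel(c), img2.channel(c))
        np.testing.assert_array_equal(gt1.ld_labels, gt2.ld_labels)

    def test_noiseless_rendering_reproduces_masks(self, noiseless_field):
        spec, image, gt = noiseless_field
        # half the foreground amplitude separates objects from background
        half = spec.background_intensity + spec.foreground_intensity * 0.4
        np.testing.assert_array_equal(
            image.channel("nuclei") > half, gt.nucleus_labels > 0
        )
        np.testing.assert_array_equal(
            image.channel("cytoplasm") > half, gt.cell_labels > 0
        )
        np.testing.assert_array_equal(image.channel("ld") > half, gt.ld_labels > 0)

    def test_area_distribution_dominated_by_small(self, small_field):
        _, _, gt = small_field
        areas = np.array(list(gt.ld_areas_um2.values()))
        assert (areas < 0.5).mean() > 0.75

    def test_planted_clusters_match_brute_force_oracle(self):
        spec = FieldSpec(seed=21, n_cells=2, width_px=768, height_px=384,
                         ld_count_per_cell=40.0, cluster_fraction=0.5)
        _, gt = generate_field(spec)
        oracle = brute_force_clusters(gt.ld_labels, gt.ld_cell)
        assert set(gt.planted_clusters) == oracle

    def test_every_droplet_inside_one_cell(self, small_field):
        _, _, gt = small_field
        for lid, cell in gt.ld_cell.items():
            mask = gt.ld_labels == lid
            assert np.all(gt.cell_labels[mask] == cell)

    def test_label_maps_nested(self, small_field):
        _, _, gt = small_field
        nz = gt.nucleus_labels > 0
        assert np.array_equal(gt.cell_labels[nz], gt.nucleus_labels[nz])

    def test_placement_infeasible_raises(self):
        spec = FieldSpec(seed=0, n_cells=9, width_px=300, height_px=300)
        with pytest.raises(PlacementError, match="cells"):
            generate_field(spec)

    def test_noise_sd_matches_snr(self):
        # blank 512^2 field: measured background s.d. within 10% of spec
        spec = FieldSpec(seed=3, snr=5.0)
        rng = np.random.default_rng(3)
        blank = _finish_channel(np.zeros((512, 512)), spec, rng)
        target = spec.foreground_intensity / spec.snr
        assert abs(blank.astype(float).std() - target) / target < 0.10


class TestGenerateTimelapse:
    def test_zero_dissociation_rate_no_events(self):
        spec = FieldSpec(seed=6, width_px=384, height_px=384, n_pairs=16)
        _, gt = generate_timelapse(spec, 60, 2, k_dissoc=0.0, k_assoc=0.0,
                                   marker_positive_fraction=0.5)
        assert not gt.event_log
        assert np.all(gt.pair_states == "A")

    def test_absorbing_dissociation(self):
        spec = FieldSpec(seed=7, width_px=384, height_px=384, n_pairs=16)
        _, gt = generate_timelapse(spec, 2000, 2, k_dissoc=0.02, k_assoc=0.0,
                                   marker_positive_fraction=0.5)
        diss = [e for e in gt.event_log if e.kind == "dissociate"]
        assert len(diss) == 16  # every pair dissociates exactly once
        assert np.all(gt.pair_states[:, -1] == "D")

    def test_marker_positive_fraction_binomial(self):
        spec = FieldSpec(seed=8, width_px=768, height_px=768, n_pairs=220)
        _, gt = generate_timelapse(spec, 400, 2, k_dissoc=0.02, k_assoc=0.0,
                                   marker_positive_fraction=0.6)
        diss = [e for e in gt.event_log if e.kind == "dissociate"]
        assert len(diss) >= 200
        frac = np.mean([e.marker_positive for e in diss])
        n = len(diss)
        ci = 1.96 * np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) <= ci + 1e-12

    def test_fusion_conserves_area(self):
        spec = FieldSpec(seed=9, width_px=384, height_px=384, n_pairs=12, snr=np.inf)
        img, gt = generate_timelapse(spec, 300, 2, k_dissoc=0.0, k_assoc=0.0,
                                     marker_positive_fraction=0.0, k_fuse=0.01)
        fused = [e for e in gt.event_log if e.kind == "fuse"]
        assert fused, "expected at least one fusion at this rate"
        ld = img.channel("ld").astype(float)
        half = spec.background_intensity + spec.foreground_intensity * 0.4
        for e in fused:
            pid = e.pair_id
            before = (_pair_crop(ld[e.frame - 1], gt.pair_centers[pid]) > half).sum()
            after = (_pair_crop(ld[e.frame], gt.pair_centers[pid]) > half).sum()
            # rendering quantization allows a few pixels of slack
            assert abs(after - before) <= 0.25 * before

    def test_event_times_ordered_per_pair(self):
        spec = FieldSpec(seed=10, width_px=512, height_px=512, n_pairs=36)
        _, gt = generate_timelapse(spec, 300, 2, k_dissoc=0.01, k_assoc=0.01,
                                   marker_positive_fraction=0.5)
        by_pair = {}
        for e in gt.event_log:
            by_pair.setdefault(e.pair_id, []).append(e.time_s)
            assert 0 <= e.time_s <= 300
        for times in by_pair.values():
            assert times == sorted(times)
            assert len(set(times)) == len(times)

    def test_invalid_timing_rejected(self):
        spec = FieldSpec(seed=1, n_pairs=4)
        with pytest.raises(ValueError):
            generate_timelapse(spec, 1.0, 2.0, 0.1, 0.1, 0.5)


def _pair_crop(frame, center, half=14):
    r, c = int(center[0]), int(center[1])
    return frame[max(r - half, 0) : r + half, max(c - half, 0) : c + half]
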