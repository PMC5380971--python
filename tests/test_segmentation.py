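import numpy as np
import pytest
from scipy import ndimage

from lipodrop.segmentation import (
    DropletRecord,
    SegmentationParams,
    _B3,
    atrous_decompose,
    atrous_reconstruct,
    detect_droplets,
    merge_fragmented,
    segment_cells,
    segment_nuclei,
)
from lipodrop.synthetic import evaluate_detection, generate_field, FieldSpec


def disc(shape, center, radius, amplitude=1000.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amplitude * (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2)


class TestSegmentNuclei:
    def test_blank_image_empty(self, default_params):
        assert segment_nuclei(np.zeros((256, 256)), default_params).max() == 0

    def test_two_planted_discs(self, default_params, rng):
        img = disc((512, 512), (130, 130), 60) + disc((512, 512), (360, 380), 60)
        img = img + rng.normal(0, 100, img.shape)  # SNR 10
        labels = segment_nuclei(img, default_params)
        assert labels.max() == 2
        for ctr in ((130, 130), (360, 380)):
            got = ndimage.center_of_mass(labels == labels[ctr])
            assert np.hypot(got[0] - ctr[0], got[1] - ctr[1]) <= 2.0

    def test_touching_nuclei_declumped(self, default_params, rng):
        # two overlapping intensity domes with a ~30% valley between peaks
        rr, cc = np.mgrid[:512, :512]
        d1 = np.hypot(rr - 250, cc - 200)
        d2 = np.hypot(rr - 250, cc - 330)
        img = 1000 * np.maximum(np.clip(1 - (d1 / 95) ** 2, 0, None),
                                np.clip(1 - (d2 / 95) ** 2, 0, None))
        img += rng.normal(0, 50, img.shape)
        labels = segment_nuclei(img, default_params)
        assert labels.max() == 2

    def test_size_gate_discards_small_and_large(self, default_params):
        img = disc((512, 512), (100, 100), 20) + disc((512, 512), (350, 350), 200)
        labels = segment_nuclei(img, default_params)
        assert labels.max() == 0

    def test_rejects_3d(self, default_params):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((4, 8, 8)), default_params)


class TestSegmentCells:
    def test_empty_nuclei_empty_cells(self, default_params):
        cells = segment_cells(np.ones((64, 64)), np.zeros((64, 64), int), default_params)
        assert cells.max() == 0

    def test_single_seed_covers_blob(self, default_params):
        img = disc((256, 256), (128, 128), 80, 1000.0)
        nuclei = (disc((256, 256), (128, 128), 30, 1) > 0).astype(int)
        cells = segment_cells(img, nuclei, default_params)
        np.testing.assert_array_equal(cells > 0, img > 500)

    def test_uniform_blob_partitioned_at_midline(self, default_params):
        # uniform intensity: propagation reduces to nearest-seed geodesic
        img = np.zeros((120, 240))
        img[40:80, 20:220] = 1000.0
        nuclei = np.zeros((120, 240), int)
        nuclei[55:65, 55:65] = 1
        nuclei[55:65, 175:185] = 2
        cells = segment_cells(img, nuclei, default_params)
        fg = img > 0
        rr, cc = np.nonzero(fg)
        # Voronoi oracle by seed-centroid distance, away from the midline
        d1 = np.hypot(rr - 59.5, cc - 59.5)
        d2 = np.hypot(rr - 59.5, cc - 179.5)
        clear = np.abs(d1 - d2) > 3
        expected = np.where(d1 < d2, 1, 2)[clear]
        assert (cells[rr[clear], cc[clear]] == expected).mean() > 0.99

    def test_each_cell_contains_its_nucleus(self, small_field, default_params):
        _, image, gt = small_field
        nuclei = segment_nuclei(image.channel("nuclei").astype(float), default_params)
        cells = segment_cells(image.channel("cytoplasm").astype(float), nuclei, default_params)
        for lab in range(1, nuclei.max() + 1):
            assert np.all(cells[nuclei == lab] == lab)


class TestAtrous:
    def test_constant_image_zero_details(self):
        planes, residual = atrous_decompose(np.full((64, 64), 7.3), 3)
        for p in planes:
            np.testing.assert_allclose(p, 0, atol=1e-12)
        np.testing.assert_allclose(residual, 7.3)

    def test_reconstruction_identity_random(self, rng):
        img = rng.normal(size=(96, 96))
        planes, residual = atrous_decompose(img, 4)
        rec = atrous_reconstruct(planes, residual)
        assert np.max(np.abs(rec - img)) < 1e-9 * max(1.0, np.max(np.abs(img)))

    def test_impulse_level1_matches_direct_convolution(self):
        # detail_1 = delta - separable B3 kernel (direct convolution oracle)
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        planes, _ = atrous_decompose(img, 1)
        kernel2d = np.outer(_B3, _B3)
        expected = img - ndimage.convolve(img, kernel2d, mode="mirror")
        np.testing.assert_allclose(planes[0], expected, atol=1e-12)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            atrous_decompose(np.zeros((32, 32)), 6)


class TestDetectDroplets:
    def test_blank_channel_no_droplets(self, default_params):
        assert detect_droplets(np.zeros((128, 128)), None, default_params, 0.133) == []

    def test_missing_calibration_errors(self, default_params):
        with pytest.raises(ValueError):
            detect_droplets(np.zeros((64, 64)), None, default_params, None)

    def test_single_gaussian_spot(self, default_params, rng):
        rr, cc = np.mgrid[:128, :128]
        spot = 1000 * np.exp(-((rr - 64.3) ** 2 + (cc - 60.7) ** 2) / (2 * 2.0**2))
        # planted half-maximum disc area, counted on the noiseless image
        expected = (spot > 500.0).sum() * 0.133**2
        areas = []
        for _ in range(5):  # average over noise draws at SNR 8
            img = spot + 100 + rng.normal(0, 125, spot.shape)
            drops = detect_droplets(img, None, default_params, 0.133)
            assert len(drops) == 1
            areas.append(drops[0].area_um2)
        assert abs(np.mean(areas) - expected) / expected <= 0.20

    def test_translation_equivariance(self, default_params, rng):
        base = np.zeros((160, 160))
        for ctr, rad in (((40, 50), 2), ((80, 100), 3), ((120, 60), 5)):
            base += disc((160, 160), ctr, rad)
        noise = rng.normal(0, 100, (160, 160))
        img = ndimage.gaussian_filter(base, 0.8) + 100 + noise
        shifted = ndimage.gaussian_filter(np.roll(base, (7, 11), (0, 1)), 0.8) + 100 + np.roll(noise, (7, 11), (0, 1))
        a = sorted(d.centroid for d in detect_droplets(img, None, default_params, 0.133))
        b = sorted(d.centroid for d in detect_droplets(shifted, None, default_params, 0.133))
        assert len(a) == len(b) == 3
        for (r1, c1), (r2, c2) in zip(a, b):
            assert abs(r2 - r1 - 7) < 0.5 and abs(c2 - c1 - 11) < 0.5

    def test_small_and_large_recall(self, default_params, rng):
        img = np.full((512, 512), 100.0)
        planted = []
        k = 0
        for i in range(8):
            for j in range(8):
                if k >= 55:
                    break
                ctr = (30 + 60 * i + rng.uniform(-5, 5), 30 + 60 * j + rng.uniform(-5, 5))
                rad = 5.5 if k < 5 else rng.uniform(1.4, 2.6)  # 5 large, 50 small
                planted.append((ctr, rad))
                img += disc((512, 512), ctr, rad)
                k += 1
        img = ndimage.gaussian_filter(img, 0.8) + rng.normal(0, 125, img.shape)
        drops = detect_droplets(img, None, default_params, 0.133)
        cents = np.array([d.centroid for d in drops])
        found_small = found_large = 0
        for (r, c), rad in planted:
            d = np.min(np.hypot(cents[:, 0] - r, cents[:, 1] - c))
            if d <= 3.0:
                if rad > 4:
                    found_large += 1
                else:
                    found_small += 1
        assert found_large / 5 >= 0.9
        assert found_small / 50 >= 0.9


class TestMergeFragmented:
    def make_record(self, img, mask, rid):
        rr, cc = np.nonzero(mask)
        return DropletRecord.from_pixels(rid, rr, cc, img, 0.133)

    def test_single_detection_unchanged(self, default_params):
        img = 100 + disc((64, 64), (32, 32), 5)
        rec = self.make_record(img, img > 500, 1)
        out = merge_fragmented([rec], img, default_params, 0.133)
        assert len(out) == 1 and out[0].n_pixels == rec.n_pixels

    def test_split_large_ld_remerged(self, default_params):
        # one large droplet artificially cut into two abutting fragments
        img = ndimage.gaussian_filter(100.0 + disc((64, 64), (32, 32), 6), 0.8)
        full = img > 550
        left = full & (np.arange(64)[None, :] < 32)
        right = full & ~left
        recs = [self.make_record(img, left, 1), self.make_record(img, right, 2)]
        out = merge_fragmented(recs, img, default_params, 0.133)
        assert len(out) == 1
        planted_area = np.pi * 6**2 * 0.133**2
        assert abs(out[0].area_um2 - planted_area) / planted_area <= 0.2

    def test_valley_prevents_merge(self):
        params = SegmentationParams(merge_valley_fraction=0.8)
        base = disc((64, 96), (32, 34), 6) + disc((64, 96), (32, 49), 6)
        img = 100.0 + base.astype(float)
        # carve a 50% valley in the 2-px corridor between the discs
        img[:, 41:43] = 100.0 + 500.0
        a = self.make_record(img, disc((64, 96), (32, 34), 6) > 0, 1)
        b = self.make_record(img, disc((64, 96), (32, 49), 6) > 0, 2)
        out = merge_fragmented([a, b], img, params, 0.133)
        assert len(out) == 2

    def test_never_shrinks_never_multiplies(self, small_field, default_params):
        spec, image, gt = small_field
        drops = detect_droplets(image.channel("ld"), None, default_params, spec.pixel_size_um)
        merged = merge_fragmented(drops, image.channel("ld"), default_params, spec.pixel_size_um)
        assert len(merged) <= len(drops)
        before = {d.id: d.area_um2 for d in drops}
        for m in merged:
            assert m.area_um2 >= before[m.id] - 1e-12


class TestEndToEnd:
    def test_planted_recovery_small_field(self, small_field, default_params):
        spec, image, gt = small_field
        nuclei = segment_nuclei(image.channel("nuclei").astype(float), default_params)
        cells = segment_cells(image.channel("cytoplasm").astype(float), nuclei, default_params)
        drops = detect_droplets(image.channel("ld"), cells, default_params, spec.pixel_size_um)
        drops = merge_fragmented(drops, image.channel("ld"), default_params, spec.pixel_size_um)
        ev = evaluate_detection(drops, gt)
        assert ev["f1"] >= 0.9
        assert np.median(ev["area_errors"]) <= 0.2
        # droplets with a cell id lie (by centroid) in that cell
        for d in drops:
            if d.cell_id is not None:
                assert cells[int(round(d.centroid[0])), int(round(d.centroid[1]))] == d.cell_id
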