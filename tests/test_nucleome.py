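"""Mask, density classes, centroids, enrichment and nearest neighbours."""
import numpy as np
import pytest
from scipy import ndimage

from coldclock import nucleome, synthgen
from coldclock.nucleome import CentroidSet, ClassMap, VoxelGrid

VOX = (0.125, 0.04, 0.04)


@pytest.fixture(scope="module")
def phantom():
    cfg = synthgen.NucleusPhantomConfig(seed=5)
    dapi, cmap, cents = synthgen.simulate_nucleus(cfg)
    return cfg, dapi, cmap, cents


class TestNuclearMask:
    def test_bright_ellipsoid_volume_matches_analytic(self):
        shape = (32, 64, 64)
        zz, yy, xx = np.indices(shape, dtype=float)
        rz, ry, rx = 12.0, 25.0, 25.0
        inside = (((zz - 15.5) / rz) ** 2 + ((yy - 31.5) / ry) ** 2
                  + ((xx - 31.5) / rx) ** 2) <= 1.0
        img = np.where(inside, 100.0, 2.0)
        mask, vol = nucleome.nuclear_mask(VoxelGrid(img, VOX))
        analytic = 4 / 3 * np.pi * (rz * VOX[0]) * (ry * VOX[1]) * (rx * VOX[2])
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            nucleome.nuclear_mask(VoxelGrid(np.zeros((8, 16, 16)), VOX))

    def test_largest_component_kept(self):
        img = np.full((16, 48, 48), 2.0)
        img[4:12, 4:20, 4:20] = 100.0   # large blob
        img[6:9, 30:36, 30:36] = 100.0  # small blob
        mask, _ = nucleome.nuclear_mask(VoxelGrid(img, VOX))
        assert mask[8, 10, 10]
        assert not mask[7, 32, 32]

    def test_dapi_phantom_mask_close_to_truth(self, phantom):
        _, dapi, cmap, _ = phantom
        mask, vol = nucleome.nuclear_mask(dapi)
        iou = (mask & cmap.mask).sum() / (mask | cmap.mask).sum()
        assert iou > 0.85


class TestSegmentClasses:
    def test_seven_level_phantom_recovered(self, phantom):
        _, dapi, cmap, _ = phantom
        est = nucleome.segment_classes(dapi, cmap.mask, seed=0)
        acc = (est.labels[cmap.mask] == cmap.labels[cmap.mask]).mean()
        assert acc >= 0.95

    def test_binary_phantom_exact(self):
        rng = np.random.default_rng(0)
        mask = np.ones((8, 24, 24), bool)
        labels = rng.integers(1, 3, mask.shape)
        img = np.where(labels == 1, 10.0, 200.0) + rng.normal(0, 1, mask.shape)
        est = nucleome.segment_classes(VoxelGrid(img, VOX), mask, n_classes=2, seed=0)
        np.testing.assert_array_equal(est.labels, labels)

    def test_deterministic(self, phantom):
        _, dapi, cmap, _ = phantom
        a = nucleome.segment_classes(dapi, cmap.mask, seed=0)
        b = nucleome.segment_classes(dapi, cmap.mask, seed=0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_class_means_increase_with_label(self, phantom):
        _, dapi, cmap, _ = phantom
        est = nucleome.segment_classes(dapi, cmap.mask, seed=0)
        means = [dapi.data[est.labels == k].mean() for k in range(1, 8)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_few_intensities_rejected(self):
        mask = np.ones((4, 8, 8), bool)
        img = np.where(np.indices(mask.shape)[2] % 2 == 0, 1.0, 2.0)
        with pytest.raises(ValueError):
            nucleome.segment_classes(VoxelGrid(img, VOX), mask, n_classes=7)

    def test_partition_sums_to_nuclear_volume(self, phantom):
        _, dapi, cmap, _ = phantom
        est = nucleome.segment_classes(dapi, cmap.mask, seed=0)
        assert est.class_volumes_um3().sum() == pytest.approx(est.nuclear_volume_um3)


class TestChromatinRatio:
    def test_all_interchromatin_is_zero(self):
        mask = np.ones((4, 8, 8), bool)
        cmap = ClassMap(np.where(mask, 1, 0).astype(np.int16), mask, VOX)
        assert nucleome.chromatin_ratio(cmap) == 0.0

    def test_forty_percent_phantom(self):
        cfg = synthgen.NucleusPhantomConfig(
            class_fractions=(0.6, 0.1, 0.08, 0.08, 0.06, 0.05, 0.03), seed=8
        )
        dapi, truth, _ = synthgen.simulate_nucleus(cfg)
        est = nucleome.segment_classes(dapi, truth.mask, seed=0)
        assert nucleome.chromatin_ratio(est) == pytest.approx(0.40, abs=0.02)

    def test_group_difference_detected_by_mann_whitney(self, rng):
        # per-nucleus ratios differing by 0.1 in truth
        a = rng.normal(0.40, 0.03, 20)
        b = rng.normal(0.50, 0.03, 20)
        _, p = nucleome.mann_whitney(a, b)
        assert p < 0.01


class TestExtractCentroids:
    def gaussian_spot(self, shape, center, sigma=(1.5, 2.0, 2.0), amp=100.0):
        zz, yy, xx = np.indices(shape, dtype=float)
        return amp * np.exp(
            -(((zz - center[0]) / sigma[0]) ** 2
              + ((yy - center[1]) / sigma[1]) ** 2
              + ((xx - center[2]) / sigma[2]) ** 2) / 2
        )

    def test_single_spot_centroid_subvoxel(self):
        img = self.gaussian_spot((20, 40, 40), (9.3, 17.6, 22.4))
        cs = nucleome.extract_centroids(VoxelGrid(img, VOX))
        assert len(cs) == 1
        vox = cs.points_um[0] / np.array(VOX)
        np.testing.assert_allclose(vox, (9.3, 17.6, 22.4), atol=0.5)

    def test_two_separated_spots(self):
        img = (self.gaussian_spot((20, 60, 60), (6, 15, 15))
               + self.gaussian_spot((20, 60, 60), (14, 45, 45)))
        assert len(nucleome.extract_centroids(VoxelGrid(img, VOX))) == 2

    def test_fused_dumbbell_split_by_watershed(self):
        img = (self.gaussian_spot((20, 40, 40), (10, 16, 20), sigma=(2, 3, 3))
               + self.gaussian_spot((20, 40, 40), (10, 24, 20), sigma=(2, 3, 3)))
        assert len(nucleome.extract_centroids(VoxelGrid(img, VOX))) == 2


class TestQualityFilter:
    def make(self, rng, n=50):
        return CentroidSet(rng.uniform(0, 2, (n, 3)), rng.uniform(0, 20, n))

    def test_zero_threshold_is_identity(self, rng):
        cs = self.make(rng)
        out = nucleome.quality_filter(cs, 0.0)
        np.testing.assert_array_equal(out.points_um, cs.points_um)

    def test_all_removed_warns(self, rng):
        cs = self.make(rng)
        with pytest.warns(UserWarning):
            out = nucleome.quality_filter(cs, 1e9)
        assert len(out) == 0

    def test_matches_brute_force(self, rng):
        cs = self.make(rng)
        out = nucleome.quality_filter(cs, 10.0)
        expected = [i for i in range(len(cs)) if cs.quality[i] >= 10.0]
        np.testing.assert_array_equal(out.points_um, cs.points_um[expected])


class TestClassEnrichment:
    def equal_volume_map(self):
        # 7 equal slabs along x
        mask = np.ones((4, 8, 70), bool)
        labels = (np.indices(mask.shape)[2] // 10 + 1).astype(np.int16)
        return ClassMap(labels, mask, VOX)

    def test_all_in_one_class_equal_volumes(self):
        cmap = self.equal_volume_map()
        # centroids all inside the class-3 slab (x voxels 20..29)
        pts = np.array([[1, 4, 25]]) * np.array(VOX) * np.ones((40, 1))
        cs = CentroidSet(pts, np.ones(40))
        prof = nucleome.class_enrichment(cs, cmap)
        enr = prof.table.set_index("class")["log2_enrichment"]
        assert enr[3] == pytest.approx(np.log2(7), abs=1e-9)
        assert (enr.drop(3) == -8.0).all()

    def test_uniform_centroids_near_zero(self, rng):
        cmap = self.equal_volume_map()
        idx = np.argwhere(cmap.mask)
        pick = idx[rng.choice(len(idx), 10_000)]
        cs = CentroidSet(pick * np.array(VOX), np.ones(10_000))
        prof = nucleome.class_enrichment(cs, cmap)
        assert prof.table["log2_enrichment"].abs().max() < 0.1

    def test_interior_marker_enriched_in_low_density_classes(self, phantom):
        cfg, _, cmap, cents = phantom
        prof = nucleome.class_enrichment(cents["interior"], cmap)
        enr = prof.table.set_index("class")["log2_enrichment"]
        assert enr[1] > 0
        assert (enr[[6, 7]] < 0).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            nucleome.class_enrichment(
                CentroidSet(np.empty((0, 3)), np.empty(0)), self.equal_volume_map()
            )


def brute_force_nn(src, dst):
    out = []
    for p in src:
        out.append(min(np.sqrt(((p - q) ** 2).sum()) for q in dst))
    return np.array(out)


class TestNNDistances:
    def test_three_four_five(self):
        src = CentroidSet(np.array([[0.0, 0.0, 0.0]]), np.ones(1))
        dst = CentroidSet(np.array([[0.0, 3.0, 4.0], [0.0, 10.0, 0.0]]), np.ones(2))
        d = nucleome.nearest_neighbor_distances(src, dst)
        assert d[0] == pytest.approx(5.0)

    def test_empty_destination_rejected(self):
        src = CentroidSet(np.array([[0.0, 0.0, 0.0]]), np.ones(1))
        with pytest.raises(ValueError):
            nucleome.nearest_neighbor_distances(
                src, CentroidSet(np.empty((0, 3)), np.empty(0))
            )

    def test_matches_brute_force(self, rng):
        a = rng.uniform(0, 5, (500, 3))
        b = rng.uniform(0, 5, (500, 3))
        d = nucleome.nearest_neighbor_distances(
            CentroidSet(a, np.ones(500)), CentroidSet(b, np.ones(500))
        )
        np.testing.assert_allclose(d, brute_force_nn(a, b), rtol=1e-12)

    def test_pooled_outlier_exclusion_hand_case(self):
        # pooled distances {1 x9, 10}: cutoff = 1.9 + 2*2.846 = 7.59 < 10
        src_pts = np.zeros((10, 3))
        dst_pts = np.zeros((10, 3))
        dst_pts[:, 2] = np.r_[np.ones(9), 10.0]
        # build 10 one-point pairs so each NPC's nearest is the paired value
        pairs = [
            (CentroidSet(src_pts[i : i + 1], np.ones(1)),
             CentroidSet(dst_pts[i : i + 1], np.ones(1)))
            for i in range(10)
        ]
        summ = nucleome.nn_distances({"only": pairs})
        row = summ.per_condition.loc["only"]
        assert row["n_excluded"] == 1
        assert row["n"] == 9
        assert row["mean_um"] == pytest.approx(1.0)

    def test_peripheral_thickening_increases_mean_distance(self):
        # directional effect, paired over seeds, via the full pipeline summary
        for seed in range(3):
            res = {}
            for name, thick in (("flat", 0.0), ("thick", 0.5)):
                cfg = synthgen.NucleusPhantomConfig(
                    seed=seed, peripheral_thickening_um=thick
                )
                _, _, cents = synthgen.simulate_nucleus(cfg)
                res[name] = nucleome.nearest_neighbor_distances(
                    cents["surface"], cents["interior"]
                ).mean()
            assert res["thick"] > res["flat"]
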