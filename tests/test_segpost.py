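"""Label post-processing, metrics, and surface extraction."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from rhinoflow.segpost import (
    MAXILLARY_COMBINED,
    MAXILLARY_LEFT,
    MAXILLARY_RIGHT,
    LabelVolume,
    dissolve_small_components,
    enforce_plausibility,
    extract_surface,
    load_nrrd,
    load_surface,
    save_nrrd,
    save_surface,
    segmentation_metrics,
    split_maxillary,
)


def volume(shape=(8, 16, 16), fill=8):
    return np.full(shape, fill, dtype=np.int16)


class TestNrrdIO:
    def test_intensity_roundtrip(self, tmp_path):
        from rhinoflow.segpost import load_intensity_nrrd, save_intensity_nrrd

        vol = np.random.default_rng(0).random((4, 6, 6))
        p = tmp_path / "inten.nrrd"
        save_intensity_nrrd(vol, p, spacing=(0.6, 0.5, 0.5))
        back, spacing, _ = load_intensity_nrrd(p)
        np.testing.assert_allclose(back, vol, atol=1e-6)
        assert spacing == pytest.approx((0.6, 0.5, 0.5))

    def test_roundtrip(self, tmp_path):
        vox = volume()
        vox[2:4, 3:6, 3:6] = 2
        lv = LabelVolume(vox, spacing=(0.6, 0.5, 0.5), origin=(1, 2, 3))
        p = tmp_path / "lab.nrrd"
        save_nrrd(lv, p)
        back = load_nrrd(p)
        np.testing.assert_array_equal(back.voxels, lv.voxels)
        assert back.spacing == pytest.approx(lv.spacing)
        assert back.origin == pytest.approx(lv.origin)


class TestSplitMaxillary:
    def test_two_boxes_assigned_left_right(self):
        vox = volume()
        vox[2:5, 4:8, 2:6] = MAXILLARY_COMBINED  # low x -> left
        vox[2:5, 4:8, 10:14] = MAXILLARY_COMBINED  # high x -> right
        out = split_maxillary(LabelVolume(vox))
        assert np.all(out.voxels[2:5, 4:8, 2:6] == MAXILLARY_LEFT)
        assert np.all(out.voxels[2:5, 4:8, 10:14] == MAXILLARY_RIGHT)
        assert "maxillary sinus right" in out.class_names.values()

    def test_empty_class_only_updates_table(self):
        lv = LabelVolume(volume())
        out = split_maxillary(lv)
        np.testing.assert_array_equal(out.voxels, lv.voxels)
        assert MAXILLARY_RIGHT in out.class_names

    def test_three_components_match_centroid_oracle(self):
        vox = volume((8, 20, 20))
        blobs = [(2, 4, 2), (2, 4, 15), (5, 10, 3)]
        for z, y, x in blobs:
            vox[z : z + 2, y : y + 3, x : x + 3] = MAXILLARY_COMBINED
        with pytest.warns(UserWarning, match="sizable components"):
            out = split_maxillary(LabelVolume(vox))
        mid = (vox.shape[2] - 1) / 2
        labels, n = ndimage.label(vox == MAXILLARY_COMBINED, np.ones((3, 3, 3)))
        for cid in range(1, n + 1):
            coords = np.argwhere(labels == cid)
            expected = MAXILLARY_LEFT if coords[:, 2].mean() < mid else MAXILLARY_RIGHT
            assert np.all(out.voxels[tuple(coords.T)] == expected)


class TestDissolve:
    def test_single_voxel_island_absorbed(self):
        vox = volume(fill=8)
        vox[4, 8, 8] = 7
        out = dissolve_small_components(LabelVolume(vox))
        assert out.voxels[4, 8, 8] == 8

    def test_component_of_exactly_min_size_untouched(self):
        vox = volume((8, 16, 16), fill=8)
        vox[3, 5, 3:13] = 7  # exactly 10 voxels
        out = dissolve_small_components(LabelVolume(vox), min_voxels=10)
        np.testing.assert_array_equal(out.voxels, vox)

    def test_speckle_matches_brute_force_neighborhood_mode_oracle(self):
        rng = np.random.default_rng(0)
        vox = np.full((6, 10, 10), 8, dtype=np.int16)
        # sparse speckles, all single-voxel components
        for _ in range(12):
            z, y, x = rng.integers(0, 6), rng.integers(0, 10), rng.integers(0, 10)
            vox[z, y, x] = rng.integers(0, 3)
        out = dissolve_small_components(LabelVolume(vox.copy()), min_voxels=10)
        # brute-force oracle: per small component voxel, neighborhood mode
        oracle = vox.copy()
        labels_all = {}
        for cid in np.unique(vox):
            lab, n = ndimage.label(vox == cid, np.ones((3, 3, 3)))
            labels_all[cid] = (lab, n)
        for z in range(6):
            for y in range(10):
                for x in range(10):
                    cid = vox[z, y, x]
                    lab, n = labels_all[cid]
                    size = (lab == lab[z, y, x]).sum()
                    if size < 10:
                        nb = vox[
                            max(z - 1, 0) : z + 2,
                            max(y - 1, 0) : y + 2,
                            max(x - 1, 0) : x + 2,
                        ]
                        vals, counts = np.unique(nb[nb != cid], return_counts=True)
                        if len(vals):
                            oracle[z, y, x] = vals[np.argmax(counts)]
        np.testing.assert_array_equal(out.voxels, oracle)

    def test_fixpoint_idempotence(self):
        rng = np.random.default_rng(1)
        vox = np.full((6, 12, 12), 8, dtype=np.int16)
        vox[rng.random((6, 12, 12)) < 0.05] = 7
        out = dissolve_small_components(LabelVolume(vox), to_fixpoint=True)
        again = dissolve_small_components(out, to_fixpoint=True)
        np.testing.assert_array_equal(out.voxels, again.voxels)


class TestPlausibility:
    def test_single_components_identity(self):
        vox = volume()
        vox[2:5, 4:8, 2:6] = 0
        out = enforce_plausibility(LabelVolume(vox), healthy=True)
        np.testing.assert_array_equal(out.voxels, vox)

    def test_blob_inside_other_sinus_recolored(self):
        vox = volume((10, 20, 20))
        vox[2:8, 4:16, 2:10] = 1  # right frontal sinus, large
        vox[4:6, 8:10, 4:6] = 3  # mislabeled blob inside it
        vox[2:4, 2:4, 16:19] = 3  # the sphenoid main component elsewhere
        out = enforce_plausibility(LabelVolume(vox), healthy=True)
        assert np.all(out.voxels[4:6, 8:10, 4:6] == 1)
        assert np.all(out.voxels[2:4, 2:4, 16:19] == 3)

    def test_unhealthy_is_noop(self):
        vox = volume()
        vox[2:4, 2:4, 2:4] = 0
        vox[6:8, 12:14, 12:14] = 0
        out = enforce_plausibility(LabelVolume(vox), healthy=False)
        np.testing.assert_array_equal(out.voxels, vox)

    def test_two_blob_case_largest_kept(self):
        vox = volume((10, 20, 20))
        vox[2:8, 4:16, 2:10] = 1  # big component of class 1
        vox[4:6, 8:10, 4:6] = 3  # small class-3 blob inside class 1's hull
        out = enforce_plausibility(LabelVolume(vox), healthy=True)
        # component-size enumeration oracle: class 3 has no main component
        # elsewhere, so its only component is the largest -> kept
        assert np.all(out.voxels[4:6, 8:10, 4:6] == 3)


class TestMetrics:
    def test_perfect_match(self):
        vox = volume()
        vox[2:4, 3:6, 3:6] = 1
        m = segmentation_metrics(vox, vox, n_classes=9)
        assert (m.accuracy, m.mean_jaccard, m.segment_match, m.component_match) == (
            100.0,
            100.0,
            100.0,
            100.0,
        )

    def test_disjoint_masks_zero_jaccard_for_class(self):
        a = np.zeros((1, 8, 8), dtype=np.int16)
        b = np.zeros((1, 8, 8), dtype=np.int16)
        a[0, :2] = 1
        b[0, 6:] = 1
        m = segmentation_metrics(a, b, n_classes=2)
        # both classes present in both but disjoint for class 1;
        # class 0 overlaps partially
        assert m.segment_match == 100.0
        assert m.mean_jaccard < 100.0

    def test_toy_pair_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, (2, 8, 8)).astype(np.int16)
        b = rng.integers(0, 3, (2, 8, 8)).astype(np.int16)
        m = segmentation_metrics(a, b, n_classes=3)
        acc = 100.0 * (a == b).mean()
        j_slices = []
        for k in range(2):
            vals = []
            for s in range(3):
                A = set(map(tuple, np.argwhere(a[k] == s)))
                B = set(map(tuple, np.argwhere(b[k] == s)))
                if not A and not B:
                    vals.append(100.0)
                else:
                    vals.append(100.0 * len(A & B) / len(A | B))
            j_slices.append(np.mean(vals))
        assert m.accuracy == pytest.approx(acc)
        assert m.mean_jaccard == pytest.approx(np.mean(j_slices))

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 4, (2, 10, 10)).astype(np.int16)
        b = rng.integers(0, 4, (2, 10, 10)).astype(np.int16)
        m1 = segmentation_metrics(a, b, n_classes=4)
        m2 = segmentation_metrics(b, a, n_classes=4)
        assert m1.accuracy == m2.accuracy
        assert m1.mean_jaccard == pytest.approx(m2.mean_jaccard)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            segmentation_metrics(np.zeros((2, 4, 4), int), np.zeros((2, 5, 5), int))


class TestSurface:
    def test_single_voxel_closed_surface(self):
        vox = np.zeros((5, 5, 5), dtype=np.int16)
        vox[2, 2, 2] = 1
        mesh = extract_surface(LabelVolume(vox), [1])
        assert mesh.is_watertight
        assert 0.1 < mesh.volume < 1.5  # of order one voxel volume

    def test_sphere_volume_within_5pct(self):
        r = 10
        zz, yy, xx = np.mgrid[:32, :32, :32]
        mask = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 < r**2
        lv = LabelVolume(mask.astype(np.int16))
        mesh = extract_surface(lv, [1])
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_stl_roundtrip(self, tmp_path):
        vox = np.zeros((6, 6, 6), dtype=np.int16)
        vox[2:4, 2:4, 2:4] = 1
        mesh = extract_surface(LabelVolume(vox), [1])
        p = tmp_path / "m.stl"
        save_surface(mesh, p)
        back = load_surface(p)
        assert len(back.faces) == len(mesh.faces)
        assert back.volume == pytest.approx(mesh.volume, rel=1e-6)

    def test_voxelization_roundtrip_overlap(self):
        # surface -> voxel mask round-trip recovers >=95% on a convex phantom
        r = 8
        zz, yy, xx = np.mgrid[:24, :24, :24]
        mask = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 < r**2
        mesh = extract_surface(LabelVolume(mask.astype(np.int16)), [1])
        from rhinoflow.meshgen import SurfaceGeometry, points_inside

        inside = points_inside(SurfaceGeometry(mesh), np.argwhere(mask).astype(float))
        assert inside.mean() >= 0.95

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_surface(LabelVolume(np.zeros((4, 4, 4), np.int16)), [1])
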