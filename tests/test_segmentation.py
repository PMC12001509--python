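import numpy as np
import pytest
from conftest import make_channel

from perimem.scene_synth import generate_scene
from perimem.segmentation import (
    LabelMap,
    build_exclusion_mask,
    detect_membrane_fragments,
    filter_fragments,
    measure_all_shapes,
    measure_shape,
    segment_nuclei,
)


class TestSegmentNuclei:
    def test_all_zero_image(self):
        lm = segment_nuclei(make_channel(np.zeros((64, 64), np.uint16), "nuclei"))
        assert lm.n_objects == 0

    def test_wrong_role_rejected(self):
        with pytest.raises(ValueError, match="nuclei"):
            segment_nuclei(make_channel(np.zeros((8, 8), np.uint16), "signal"))

    def test_recovers_ground_truth_disks_exactly(self, noisefree_spec):
        image, truth = generate_scene(noisefree_spec)
        lm = segment_nuclei(make_channel(image[0], "nuclei"), min_area_px=50)
        assert lm.n_objects == truth.n_placed == 5
        # noise-free two-level image: thresholded support equals the truth
        np.testing.assert_array_equal(lm.labels > 0, truth.nucleus_labels > 0)
        # and each connected object matches exactly one truth disk
        for label in range(1, lm.n_objects + 1):
            truth_ids = np.unique(truth.nucleus_labels[lm.labels == label])
            assert len(truth_ids) == 1
            np.testing.assert_array_equal(
                lm.labels == label, truth.nucleus_labels == truth_ids[0]
            )

    def test_disk_area_close_to_analytic(self, disk_image):
        lm = segment_nuclei(make_channel(disk_image, "nuclei"), min_area_px=10)
        assert lm.n_objects == 1
        area = int((lm.labels == 1).sum())
        assert area == pytest.approx(np.pi * 20**2, rel=0.05)

    def test_min_area_filters_specks(self, disk_image):
        img = disk_image.copy()
        img[2, 2] = 3000  # single bright pixel
        lm = segment_nuclei(make_channel(img, "nuclei"), min_area_px=10)
        assert lm.n_objects == 1


class TestExclusionMask:
    def _single_pixel_map(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[4, 4] = 1
        return LabelMap(labels=labels, n_objects=1)

    def test_distance_zero_is_identity(self, noisefree_spec):
        image, truth = generate_scene(noisefree_spec)
        lm = segment_nuclei(make_channel(image[0], "nuclei"))
        mask = build_exclusion_mask(lm, 0.0)
        np.testing.assert_array_equal(mask, lm.labels > 0)

    def test_single_pixel_radius_one_is_plus_shape(self):
        mask = build_exclusion_mask(self._single_pixel_map(), 1.0)
        expected = np.zeros((9, 9), dtype=bool)
        for r, c in [(4, 4), (3, 4), (5, 4), (4, 3), (4, 5)]:
            expected[r, c] = True
        np.testing.assert_array_equal(mask, expected)

    @pytest.mark.parametrize("d1,d2", [(0.0, 1.0), (1.0, 2.5), (3.0, 10.0)])
    def test_monotone_in_distance(self, d1, d2):
        lm = self._single_pixel_map()
        m1 = build_exclusion_mask(lm, d1)
        m2 = build_exclusion_mask(lm, d2)
        assert (m1 <= m2).all()

    def test_empty_map_gives_empty_mask(self):
        lm = LabelMap(labels=np.zeros((5, 5), dtype=np.int32), n_objects=0)
        assert not build_exclusion_mask(lm, 4.0).any()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            build_exclusion_mask(self._single_pixel_map(), -1.0)


def _scene_with_exclusion(spec, distance=None):
    image, truth = generate_scene(spec)
    nuclei = segment_nuclei(make_channel(image[0], "nuclei"))
    if distance is None:
        distance = 10.0
    exclusion = build_exclusion_mask(nuclei, distance)
    return image, truth, exclusion


class TestDetectMembraneFragments:
    def test_zero_signal(self):
        signal = make_channel(np.zeros((64, 64), np.uint16), "signal")
        lm = detect_membrane_fragments(signal, np.zeros((64, 64), bool))
        assert lm.n_objects == 0

    def test_objects_subset_of_truth_membrane(self, noisefree_spec):
        image, truth, exclusion = _scene_with_exclusion(noisefree_spec)
        lm = detect_membrane_fragments(make_channel(image[1], "signal"), exclusion)
        assert lm.n_objects > 0
        detected = lm.labels > 0
        assert (detected & ~(truth.membrane_labels > 0)).sum() == 0

    def test_exclusion_removes_halo_level_pixels(self, noisefree_spec):
        image, truth, tight = _scene_with_exclusion(noisefree_spec, distance=0.0)
        _, _, wide = _scene_with_exclusion(noisefree_spec, distance=10.0)
        signal = make_channel(image[1], "signal")
        halo_value = noisefree_spec.perinuclear_intensity
        lm_tight = detect_membrane_fragments(signal, tight)
        lm_wide = detect_membrane_fragments(signal, wide)
        pooled_tight = image[1][lm_tight.labels > 0]
        pooled_wide = image[1][lm_wide.labels > 0]
        assert (pooled_tight == halo_value).any()
        assert not (pooled_wide == halo_value).any()

    def test_no_object_inside_exclusion(self, noisefree_spec):
        image, _, exclusion = _scene_with_exclusion(noisefree_spec)
        lm = detect_membrane_fragments(make_channel(image[1], "signal"), exclusion)
        assert (lm.labels[exclusion] == 0).all()

    def test_unknown_method_rejected(self):
        signal = make_channel(np.ones((8, 8), np.uint16), "signal")
        with pytest.raises(ValueError, match="threshold method"):
            detect_membrane_fragments(
                signal, np.zeros((8, 8), bool), threshold_method="magic"
            )

    def test_fixed_and_quantile_methods(self):
        px = np.zeros((32, 32), np.uint16)
        px[10:20, 10:12] = 500
        signal = make_channel(px, "signal")
        none = np.zeros((32, 32), bool)
        lm = detect_membrane_fragments(
            signal, none, threshold_method="fixed", threshold_value=400
        )
        assert lm.n_objects == 1
        lm = detect_membrane_fragments(
            signal, none, threshold_method="quantile", threshold_quantile=0.95
        )
        assert lm.n_objects == 1

    def test_shape_mismatch_rejected(self):
        signal = make_channel(np.zeros((8, 8), np.uint16), "signal")
        with pytest.raises(ValueError, match="shape"):
            detect_membrane_fragments(signal, np.zeros((4, 4), bool))


def _bar_map(width=3, length=100, pad=5):
    labels = np.zeros((width + 2 * pad, length + 2 * pad), dtype=np.int32)
    labels[pad : pad + width, pad : pad + length] = 1
    return LabelMap(labels=labels, n_objects=1)


def _disk_map(radius, pad=5):
    size = 2 * (radius + pad) + 1
    rows, cols = np.mgrid[0:size, 0:size]
    disk = np.hypot(rows - size // 2, cols - size // 2) <= radius
    return LabelMap(labels=disk.astype(np.int32), n_objects=1)


class TestMeasureShape:
    def test_square_form_factor_near_analytic(self):
        # continuous square: 4*pi*s^2 / (4s)^2 = pi/4
        for s in (20, 40):
            labels = np.zeros((s + 10, s + 10), dtype=np.int32)
            labels[5 : 5 + s, 5 : 5 + s] = 1
            m = measure_shape(LabelMap(labels=labels, n_objects=1), 1)
            assert m.area_px == s * s
            assert m.circularity == pytest.approx(np.pi / 4, rel=0.15)

    def test_disk_scores_near_one(self):
        m = measure_shape(_disk_map(30), 1)
        assert m.circularity >= 0.85

    def test_thin_bar_scores_low(self):
        # analytic 4*pi*300/206^2 ~= 0.089
        m = measure_shape(_bar_map(), 1)
        assert m.circularity < 0.3
        analytic = 4 * np.pi * 300 / 206**2
        assert analytic / 2 < m.circularity < analytic * 2

    def test_missing_label(self):
        with pytest.raises(KeyError):
            measure_shape(_bar_map(), 2)

    def test_area_equals_pixel_count(self, noisefree_spec):
        image, truth, exclusion = _scene_with_exclusion(noisefree_spec)
        lm = detect_membrane_fragments(make_channel(image[1], "signal"), exclusion)
        table = measure_all_shapes(lm)
        for row in table.itertuples():
            assert row.area_px == int((lm.labels == row.label).sum())


class TestFilterFragments:
    def _combined_map(self):
        bar = _bar_map().labels
        disk = _disk_map(15).labels
        h = max(bar.shape[0], disk.shape[0])
        canvas = np.zeros((h, bar.shape[1] + disk.shape[1] + 5), dtype=np.int32)
        canvas[: bar.shape[0], : bar.shape[1]] = bar
        canvas[: disk.shape[0], bar.shape[1] + 5 :][disk > 0] = 2
        return LabelMap(labels=canvas, n_objects=2)

    def test_disk_removed_arc_kept(self):
        lm = self._combined_map()
        table = measure_all_shapes(lm)
        out, mapping = filter_fragments(lm, table, (50, 10000), 0.3)
        assert out.n_objects == 1
        assert mapping == {1: 1}  # the bar survives, relabelled to 1
        assert (out.labels[lm.labels == 2] == 0).all()

    def test_empty_input(self):
        lm = LabelMap(labels=np.zeros((5, 5), dtype=np.int32), n_objects=0)
        out, mapping = filter_fragments(lm, measure_all_shapes(lm))
        assert out.n_objects == 0 and mapping == {}

    def test_idempotent(self):
        lm = self._combined_map()
        table = measure_all_shapes(lm)
        once, _ = filter_fragments(lm, table, (50, 10000), 0.3)
        twice, mapping = filter_fragments(
            once, measure_all_shapes(once), (50, 10000), 0.3
        )
        np.testing.assert_array_equal(once.labels, twice.labels)
        assert mapping == {i: i for i in range(1, once.n_objects + 1)}

    def test_incomplete_shape_table_rejected(self):
        lm = self._combined_map()
        table = measure_all_shapes(lm)
        with pytest.raises(ValueError, match="misses"):
            filter_fragments(lm, table[table["label"] == 1])


class TestRecoveryInvariant:
    def test_noisefree_recovery_and_exclusion(self, noisefree_spec):
        """>=90% of eligible truth membrane pixels recovered; zero retained
        pixels in truth nucleus or halo regions."""
        from skimage import measure as skmeasure

        image, truth, exclusion = _scene_with_exclusion(noisefree_spec)
        lm = detect_membrane_fragments(make_channel(image[1], "signal"), exclusion)
        retained, _ = filter_fragments(lm, measure_all_shapes(lm), (50, 50000), 0.3)
        got = retained.labels > 0
        assert (got & (truth.nucleus_labels > 0)).sum() == 0
        assert (got & (truth.halo_labels > 0)).sum() == 0
        eligible = skmeasure.label(
            (truth.membrane_labels > 0) & ~exclusion, connectivity=2
        )
        counts = np.bincount(eligible.ravel())
        big = np.flatnonzero(counts >= 50)
        big = big[big > 0]
        eligible_mask = np.isin(eligible, big)
        coverage = (got & eligible_mask).sum() / eligible_mask.sum()
        assert coverage >= 0.90
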