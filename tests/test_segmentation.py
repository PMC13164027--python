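"""Mask IO, instance postprocessing, fallback segmentation, external adapter."""

import numpy as np
import pytest

from dabquant import (
    InstanceMask,
    SyntheticSpec,
    fallback_segment,
    generate_tile,
    load_instance_mask,
    postprocess_instances,
    run_external_segmenter,
    save_instance_mask,
)
from dabquant.errors import FormatError, OptionalDependencyError, ParameterError

from conftest import random_instance_mask


class TestMaskIO:
    def test_round_trip_16bit_png(self, tmp_path):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[1:4, 1:4] = 1
        labels[6:9, 6:9] = 2
        path = tmp_path / "mask.png"
        save_instance_mask(InstanceMask(labels=labels), path)
        loaded = load_instance_mask(path)
        assert loaded.n_nuclei == 2
        assert np.array_equal(loaded.labels, labels)

    def test_all_zero_raster_has_no_nuclei(self, tmp_path):
        path = tmp_path / "empty.png"
        save_instance_mask(InstanceMask(labels=np.zeros((5, 5), dtype=np.int32)), path)
        assert load_instance_mask(path).n_nuclei == 0

    def test_rgb_file_rejected_with_informative_error(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((5, 5, 3), dtype=np.uint8))
        with pytest.raises(FormatError, match="single-channel"):
            load_instance_mask(path)

    def test_float_array_rejected(self):
        with pytest.raises(FormatError, match="integer"):
            InstanceMask(labels=np.zeros((5, 5), dtype=float))


def _square(labels, r, c, side, value):
    labels[r : r + side, c : c + side] = value


class TestPostprocess:
    def test_small_object_removed_large_retained(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[1:2, 1:20] = 1  # 19 px
        _square(labels, 10, 10, 5, 2)  # 25 px
        out = postprocess_instances(InstanceMask(labels=labels), min_area=20)
        assert out.n_nuclei == 1
        assert list(out.areas().values()) == [25]

    def test_exactly_min_area_object_survives(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[1:2, 1:21] = 1  # exactly 20 px
        out = postprocess_instances(InstanceMask(labels=labels), min_area=20)
        assert out.n_nuclei == 1

    def test_donut_filled_to_full_disk(self):
        from skimage.draw import disk

        labels = np.zeros((40, 40), dtype=np.int32)
        rr, cc = disk((20, 20), 10)
        labels[rr, cc] = 1
        hole_rr, hole_cc = disk((20, 20), 4)
        disk_area = len(rr)
        labels[hole_rr, hole_cc] = 0
        out = postprocess_instances(InstanceMask(labels=labels))
        assert out.n_nuclei == 1
        assert list(out.areas().values()) == [disk_area]

    def test_fill_holes_never_steals_other_nuclei(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:30, 5:30] = 1
        labels[10:20, 10:20] = 0  # hole in object 1 ...
        _square(labels, 12, 12, 5, 2)  # ... containing object 2
        out = postprocess_instances(InstanceMask(labels=labels))
        areas = out.areas()
        assert out.n_nuclei == 2
        assert 25 in areas.values()  # object 2 untouched

    def test_fragments_of_same_label_merge_when_filling_bridges_them(self):
        # a ring and an island inside its hole share one label; filling the
        # ring's hole makes the fragments adjacent, so they merge into one
        # object; without joint merging they remain two objects
        from skimage.draw import disk

        labels = np.zeros((40, 40), dtype=np.int32)
        rr, cc = disk((20, 20), 12)
        labels[rr, cc] = 1
        hole_rr, hole_cc = disk((20, 20), 6)
        labels[hole_rr, hole_cc] = 0
        labels[18:23, 18:23] = 1  # 25-px island fragment, not touching the ring
        merged = postprocess_instances(InstanceMask(labels=labels), merge_fragments=True)
        split = postprocess_instances(InstanceMask(labels=labels), merge_fragments=False)
        assert merged.n_nuclei == 1
        assert merged.areas()[1] == len(rr)  # the filled disk
        assert split.n_nuclei == 2

    def test_idempotent_on_random_masks(self, rng):
        for _ in range(50):
            labels = random_instance_mask(rng)
            once = postprocess_instances(InstanceMask(labels=labels))
            twice = postprocess_instances(once)
            assert np.array_equal(once.labels, twice.labels)

    def test_labels_contiguous_and_scan_ordered(self, rng):
        labels = random_instance_mask(rng, n_blobs=6)
        out = postprocess_instances(InstanceMask(labels=labels))
        ids = out.ids
        assert list(ids) == list(range(1, out.n_nuclei + 1))
        firsts = [np.flatnonzero(out.labels.ravel() == i)[0] for i in ids]
        assert firsts == sorted(firsts)

    def test_output_never_grows_foreground_without_fill_and_respects_min_area(self, rng):
        for _ in range(10):
            labels = random_instance_mask(rng)
            before = np.count_nonzero(labels)
            removed = postprocess_instances(InstanceMask(labels=labels), fill_holes=False)
            assert np.count_nonzero(removed.labels) <= before
            full = postprocess_instances(InstanceMask(labels=labels))
            assert all(a >= 20 for a in full.areas().values())

    def test_min_area_below_one_rejected(self):
        with pytest.raises(ParameterError):
            postprocess_instances(InstanceMask(labels=np.zeros((4, 4), dtype=np.int32)), min_area=0)


class TestFallbackSegment:
    def test_recovers_exact_count_on_disjoint_tile(self, balanced_tile):
        mask = fallback_segment(balanced_tile.rgb)
        assert mask.n_nuclei == balanced_tile.mask.n_nuclei

    def test_blank_white_tile_yields_empty_mask(self):
        white = np.full((64, 64, 3), 255, dtype=np.uint8)
        mask = fallback_segment(white)
        assert mask.n_nuclei == 0

    def test_deterministic(self, balanced_tile):
        a = fallback_segment(balanced_tile.rgb)
        b = fallback_segment(balanced_tile.rgb)
        assert np.array_equal(a.labels, b.labels)

    def test_splits_slightly_overlapping_pair(self):
        tile = generate_tile(
            SyntheticSpec(
                height=96,
                width=96,
                n_per_class=(2, 0, 0, 0),
                radius_range=(10, 12),
                overlap_fraction=0.15,
                spacing=0,
                seed=11,
            )
        )
        assert tile.mask.n_nuclei == 2
        mask = fallback_segment(tile.rgb)
        assert mask.n_nuclei == 2


class _StubAdapter:
    def __init__(self, labels):
        self.labels = labels

    def segment(self, rgb):
        return self.labels


class TestExternalAdapter:
    def test_missing_dependency_raises_actionable_error(self):
        rgb = np.full((8, 8, 3), 255, dtype=np.uint8)
        with pytest.raises(OptionalDependencyError, match="cellpose"):
            run_external_segmenter(rgb)

    def test_stub_labels_pass_through_postprocessing(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:9, 2:9] = 5  # 49 px, survives
        rgb = np.full((32, 32, 3), 255, dtype=np.uint8)
        out = run_external_segmenter(rgb, adapter=_StubAdapter(labels))
        assert out.n_nuclei == 1
        assert list(out.ids) == [1]  # relabeled

    def test_stub_small_object_removed_by_shared_postprocessing(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[1:2, 1:20] = 1  # 19 px
        rgb = np.full((32, 32, 3), 255, dtype=np.uint8)
        out = run_external_segmenter(rgb, adapter=_StubAdapter(labels))
        assert out.n_nuclei == 0
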