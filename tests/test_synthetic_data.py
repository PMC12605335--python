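"""Synthetic dataset generator and split machinery."""

import numpy as np
import pytest

from lessnet.data import (ImageSample, SyntheticConfig, generate_dataset,
                          labeled_count, read_dataset, read_split,
                          split_dataset, write_dataset, write_manifest)


class TestGenerator:
    def test_zero_samples(self, tiny_config):
        assert generate_dataset(0, tiny_config) == []

    def test_seeded_determinism_byte_identical(self):
        cfg = SyntheticConfig(image_size=48, seed=7,
                              lesion_area_fraction_range=(0.02, 0.2))
        a = generate_dataset(5, cfg)
        b = generate_dataset(5, cfg)
        for s, t in zip(a, b):
            assert s.id == t.id
            assert np.array_equal(s.image, t.image)
            assert np.array_equal(s.mask, t.mask)

    def test_different_seeds_differ(self):
        a = generate_dataset(1, SyntheticConfig(image_size=48, seed=1))[0]
        b = generate_dataset(1, SyntheticConfig(image_size=48, seed=2))[0]
        assert not np.array_equal(a.image, b.image)

    def test_area_fraction_bounds_hold_for_every_mask(self):
        """Foreground fraction verified by brute-force pixel count."""
        lo, hi = 0.01, 0.10
        cfg = SyntheticConfig(image_size=64, seed=11,
                              lesion_area_fraction_range=(lo, hi))
        for s in generate_dataset(100, cfg):
            frac = int(s.mask.sum()) / s.mask.size
            assert lo <= frac <= hi
            assert s.mask.sum() >= 1

    def test_mask_binary_and_shapes(self, tiny_dataset):
        for s in tiny_dataset:
            assert s.image.shape[:2] == s.mask.shape
            assert set(np.unique(s.mask)) <= {0, 1}
            assert s.image.dtype == np.uint8

    def test_lesion_kind_coverage(self):
        for kind in ("point", "extensive", "trapezoidal", "vessel"):
            cfg = SyntheticConfig(image_size=48, seed=3, lesion_kinds=(kind,),
                                  lesion_area_fraction_range=(0.02, 0.08))
            s = generate_dataset(2, cfg)
            assert all(x.mask.sum() >= 1 for x in s)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(lesion_area_fraction_range=(0.2, 0.1))
        with pytest.raises(ValueError):
            SyntheticConfig(lesion_area_fraction_range=(0.0, 0.1))
        with pytest.raises(ValueError):
            SyntheticConfig(lesion_kinds=("nope",))
        with pytest.raises(ValueError):
            generate_dataset(-1, SyntheticConfig())

    def test_invalid_sample_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            ImageSample(id="x", image=img, mask=np.full((8, 8), 2))
        with pytest.raises(ValueError):
            ImageSample(id="x", image=img, mask=np.zeros((4, 4)))


class TestSplits:
    def test_405_images_split_8_to_2(self):
        samples = [ImageSample(id=f"s{i}", image=np.zeros((8, 8, 3), dtype=np.uint8),
                               mask=np.zeros((8, 8), dtype=np.uint8))
                   for i in range(405)]
        split = split_dataset(samples, test_fraction=0.2, label_ratio=0.5, seed=0)
        assert len(split.train) == 324
        assert len(split.test) == 81
        assert len(split.labeled_ids) == 162

    @pytest.mark.parametrize("n_train,ratio,expected",
                             [(324, 0.50, 162), (324, 0.25, 81), (324, 0.05, 16)])
    def test_labeled_count_floor_rule(self, n_train, ratio, expected):
        assert labeled_count(n_train, ratio) == expected

    def test_zero_labeled_raises(self):
        with pytest.raises(ValueError):
            labeled_count(10, 0.05)

    def test_partition_conservation_and_disjointness(self, tiny_dataset):
        split = split_dataset(tiny_dataset, test_fraction=0.25, label_ratio=0.5, seed=3)
        assert len(split.train) + len(split.test) == len(tiny_dataset)
        assert not ({s.id for s in split.train} & {s.id for s in split.test})
        assert split.labeled_ids <= {s.id for s in split.train}

    def test_split_determinism(self, tiny_dataset):
        a = split_dataset(tiny_dataset, 0.25, 0.5, seed=9)
        b = split_dataset(tiny_dataset, 0.25, 0.5, seed=9)
        assert [s.id for s in a.train] == [s.id for s in b.train]
        assert a.labeled_ids == b.labeled_ids

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], 0.2, 0.5, seed=0)


class TestRoundTrip:
    def test_dataset_and_manifest_roundtrip(self, tiny_dataset, tmp_path):
        write_dataset(tiny_dataset[:6], tmp_path)
        split = split_dataset(tiny_dataset[:6], 0.34, 0.5, seed=0)
        write_manifest(split, tmp_path / "split.json")
        loaded = read_dataset(tmp_path)
        by_id = {s.id: s for s in loaded}
        for s in tiny_dataset[:6]:
            assert np.array_equal(by_id[s.id].image, s.image)
            assert np.array_equal(by_id[s.id].mask, s.mask)
        split2 = read_split(tmp_path)
        assert {s.id for s in split2.train} == {s.id for s in split.train}
        assert split2.labeled_ids == split.labeled_ids
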