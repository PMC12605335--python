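"""Weak/strong view policies and offline expansion."""

import numpy as np
import pytest

from lessnet.augment import (STRONG_DEFAULT, WEAK_DEFAULT, AugmentationPolicy,
                             expand_offline, sample_params, strong_augment,
                             weak_augment)
from lessnet.data import ImageSample


def half_foreground_sample(size=16):
    img = np.full((size, size, 3), 120, dtype=np.uint8)
    img[:, : size // 2] = 40
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[:, : size // 2] = 1
    return ImageSample(id="half", image=img, mask=mask)


class TestPolicies:
    def test_weak_policy_invariant_enforced(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(strength="weak", rotation_limit_deg=5.0)

    def test_strong_policy_is_superset(self):
        assert STRONG_DEFAULT.hflip_probability == WEAK_DEFAULT.hflip_probability
        assert STRONG_DEFAULT.brightness_delta == WEAK_DEFAULT.brightness_delta
        assert STRONG_DEFAULT.rotation_limit_deg == 20.0
        assert STRONG_DEFAULT.saturation_delta > 0
        assert STRONG_DEFAULT.hue_delta > 0

    def test_rotation_angles_bounded_by_20_degrees(self, rng):
        angles = [sample_params(STRONG_DEFAULT, np.random.default_rng(s))["angle"]
                  for s in range(1000)]
        assert all(-20.0 <= a <= 20.0 for a in angles)
        assert max(angles) > 10 and min(angles) < -10  # the range is used


class TestWeakAugment:
    def test_seeded_determinism(self, tiny_dataset):
        s = tiny_dataset[0]
        a = weak_augment(s, seed=5)
        b = weak_augment(s, seed=5)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_identity_policy_is_identity(self, tiny_dataset):
        s = tiny_dataset[0]
        ident = AugmentationPolicy(strength="weak", hflip_probability=0.0,
                                   brightness_delta=0.0,
                                   contrast_factor_range=(1.0, 1.0))
        out = weak_augment(s, seed=0, policy=ident)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)

    def test_flip_moves_mask_to_other_half(self):
        s = half_foreground_sample()
        flip_policy = AugmentationPolicy(strength="weak", hflip_probability=1.0,
                                         brightness_delta=0.0,
                                         contrast_factor_range=(1.0, 1.0))
        out = weak_augment(s, seed=1, policy=flip_policy)
        expected = s.mask[:, ::-1]
        assert np.array_equal(out.mask, expected)
        assert out.mask[:, : 8].sum() == 0

    def test_photometric_ops_leave_mask_untouched(self, tiny_dataset):
        s = tiny_dataset[1]
        noflip = AugmentationPolicy(strength="weak", hflip_probability=0.0)
        out = weak_augment(s, seed=3, policy=noflip)
        assert np.array_equal(out.mask, s.mask)
        assert out.image.shape == s.image.shape


class TestStrongAugment:
    def test_mask_stays_binary_over_many_seeds(self, tiny_dataset):
        s = tiny_dataset[2]
        for seed in range(100):
            out = strong_augment(s, seed=seed)
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_zero_policy_identity(self, tiny_dataset):
        s = tiny_dataset[0]
        ident = AugmentationPolicy(strength="strong", hflip_probability=0.0,
                                   brightness_delta=0.0,
                                   contrast_factor_range=(1.0, 1.0),
                                   rotation_limit_deg=0.0, saturation_delta=0.0,
                                   hue_delta=0.0)
        out = strong_augment(s, seed=0, policy=ident)
        assert np.array_equal(out.image, s.image)

    def test_differs_from_weak_view_in_general(self, tiny_dataset):
        s = tiny_dataset[3]
        diffs = sum(not np.array_equal(weak_augment(s, seed).image,
                                       strong_augment(s, seed).image)
                    for seed in range(5))
        assert diffs >= 4

    def test_spatial_size_preserved(self, tiny_dataset):
        out = strong_augment(tiny_dataset[0], seed=9)
        assert out.image.shape == tiny_dataset[0].image.shape


class TestViewAlignment:
    """Undoing a view's geometry maps its content back to the original
    frame — the property the consistency loss relies on."""

    @pytest.mark.parametrize("maker", ["weak", "strong"])
    def test_inverse_alignment_restores_original_frame(self, tiny_dataset, maker):
        from lessnet.augment import strong_view, weak_view
        from lessnet.nn import Tensor
        from lessnet.training import _align_view
        make = weak_view if maker == "weak" else strong_view
        s = tiny_dataset[4]
        disagreements = []
        for seed in range(10):
            view, params = make(s, seed)
            carried = view.mask.astype(np.float32)[None, None]
            aligned = _align_view(Tensor(carried), [params]).data[0, 0]
            inner = slice(8, -8)  # rotation clamps the border
            disagreements.append(
                ((aligned > 0.5) ^ s.mask.astype(bool))[inner, inner].mean())
        assert float(np.mean(disagreements)) < 0.01


class TestOfflineExpansion:
    def test_expansion_counts(self, tiny_dataset):
        assert len(expand_offline(tiny_dataset[:3], seed=0)) == 15
        assert len(expand_offline([tiny_dataset[0]], seed=0)) == 5
        assert expand_offline([], seed=0) == []

    def test_variants_carry_derived_ids_and_masks(self, tiny_dataset):
        out = expand_offline(tiny_dataset[:2], seed=0)
        ids = [s.id for s in out]
        assert ids[0] == tiny_dataset[0].id
        assert ids[1].startswith(tiny_dataset[0].id + "_aug")
        assert len(set(ids)) == len(ids)
        for s in out:
            assert s.mask is not None
            assert set(np.unique(s.mask)) <= {0, 1}

    def test_missing_mask_rejected(self):
        bare = ImageSample(id="x", image=np.zeros((8, 8, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            expand_offline([bare], seed=0)

    def test_expansion_determinism(self, tiny_dataset):
        a = expand_offline(tiny_dataset[:2], seed=4)
        b = expand_offline(tiny_dataset[:2], seed=4)
        for s, t in zip(a, b):
            assert np.array_equal(s.image, t.image)
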