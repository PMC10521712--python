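"""Synthetic generation, I/O round trips, augmentation, fold schemes."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from joshua_seg.data_pipeline import (AugmentConfig, GenerationError,
                                      HistImage, SyntheticSpec, augment,
                                      generate_synthetic_dataset, load_mask,
                                      load_pair, make_folds,
                                      render_synthetic_scene, resize_pair,
                                      save_pair, FOLD_SCHEMES)

from oracles import loop_ellipse_interior_count

RNG = np.random.default_rng(5)


def cyclic_labels(ids):
    weeks = (1, 2, 4, 8)
    conds = ("a", "b", "c", "d")
    return {i: {"week": weeks[n % 4], "condition": conds[(n // 4) % 4]}
            for n, i in enumerate(ids)}


class TestSyntheticGeneration:
    def test_mask_matches_point_in_ellipse_oracle(self):
        spec = SyntheticSpec(height=48, width=48, seed=3)
        img, mask, ellipses = render_synthetic_scene(
            spec, np.random.default_rng(3))
        assert mask.sum() == loop_ellipse_interior_count(48, 48, ellipses)

    def test_adipose_poor_regime(self):
        spec = SyntheticSpec(height=64, width=64,
                             adipose_fraction_range=(0.0, 0.01),
                             n_blobs_range=(0, 2), blob_axis_range=(2, 4))
        rng = np.random.default_rng(0)
        for _ in range(5):
            _, mask, _ = render_synthetic_scene(spec, rng)
            assert mask.mean() < 0.01

    def test_adipose_rich_regime(self):
        spec = SyntheticSpec(height=64, width=64,
                             adipose_fraction_range=(0.10, 0.40))
        rng = np.random.default_rng(1)
        for _ in range(5):
            _, mask, _ = render_synthetic_scene(spec, rng)
            assert 0.10 <= mask.mean() <= 0.40

    def test_zero_blobs_gives_background_only(self):
        spec = SyntheticSpec(adipose_fraction_range=(0.0, 0.0),
                             n_blobs_range=(0, 0))
        img, mask, ellipses = render_synthetic_scene(
            spec, np.random.default_rng(0))
        assert mask.sum() == 0 and not ellipses
        assert img.std() > 0          # still stain-textured

    def test_infeasible_constraints_raise_generation_error(self):
        # huge mandatory fraction with tiny blobs cannot be satisfied
        spec = SyntheticSpec(height=32, width=32,
                             adipose_fraction_range=(0.9, 0.95),
                             n_blobs_range=(1, 1), blob_axis_range=(2, 3))
        with pytest.raises(GenerationError, match="fraction"):
            render_synthetic_scene(spec, np.random.default_rng(0))

    def test_generation_is_pure_function_of_spec(self, tmp_path):
        spec = SyntheticSpec(n_images=4, height=32, width=32, seed=9)
        a = generate_synthetic_dataset(spec, tmp_path / "a")
        b = generate_synthetic_dataset(spec, tmp_path / "b")
        assert list(a["id"]) == list(b["id"])
        for rel in ("images/synth_0000.png", "masks/synth_0003.png"):
            ha = hashlib.sha256((tmp_path / "a" / rel).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / rel).read_bytes()).hexdigest()
            assert ha == hb

    def test_manifest_covers_weeks_and_conditions(self, tmp_path):
        spec = SyntheticSpec(n_images=16, height=32, width=32, seed=2)
        manifest = generate_synthetic_dataset(spec, tmp_path)
        assert sorted(manifest["week"].unique()) == [1, 2, 4, 8]
        assert manifest["reference_length_um_per_px"].nunique() == 1


class TestIO:
    def test_round_trip_is_lossless(self, tmp_path):
        spec = SyntheticSpec(height=32, width=32)
        img, mask, _ = render_synthetic_scene(spec, np.random.default_rng(4))
        quantized = np.round(img * 255) / 255
        save_pair(HistImage(img, id="x"), mask, tmp_path / "i.png",
                  tmp_path / "m.png")
        img2, mask2 = load_pair(tmp_path / "i.png", tmp_path / "m.png")
        np.testing.assert_array_equal(mask2, mask)          # mask lossless
        np.testing.assert_allclose(img2.pixels, quantized)  # 8-bit exact

    def test_mismatched_dims_rejected(self, tmp_path):
        img = HistImage(RNG.random((16, 16, 3)))
        save_pair(img, np.zeros((16, 16), np.uint8), tmp_path / "i.png",
                  tmp_path / "m.png")
        save_pair(HistImage(RNG.random((8, 8, 3))),
                  np.zeros((8, 8), np.uint8), tmp_path / "i2.png",
                  tmp_path / "m2.png")
        with pytest.raises(ValueError, match="disagree"):
            load_pair(tmp_path / "i.png", tmp_path / "m2.png")

    def test_non_binary_mask_rejected(self, tmp_path):
        from PIL import Image
        Image.fromarray(np.full((8, 8), 127, np.uint8)).save(tmp_path / "m.png")
        with pytest.raises(ValueError, match="binary"):
            load_mask(tmp_path / "m.png")

    def test_resize_keeps_masks_binary_and_constants_constant(self):
        img = HistImage(np.full((64, 64, 3), 0.25))
        mask = (RNG.random((64, 64)) < 0.3).astype(np.uint8)
        small, small_mask = resize_pair(img, mask, (32, 32))
        assert set(np.unique(small_mask)) <= {0, 1}
        np.testing.assert_allclose(small.pixels, 0.25)
        assert small.metadata["original_height"] == 64


class TestAugment:
    def _pair(self):
        spec = SyntheticSpec(height=32, width=32)
        img, mask, _ = render_synthetic_scene(spec, np.random.default_rng(8))
        return HistImage(img, id="p"), mask

    def test_noop_draw_path_returns_input(self):
        img, mask = self._pair()
        cfg = AugmentConfig(flip_p=0.0, jitter_p=0.0, hue_p=0.0)
        for seed in range(50):       # find a seed whose rotation draw is 0
            probe = np.random.default_rng(seed)
            probe.random()           # the (disabled) flip draw comes first
            if probe.integers(0, 4) == 0:
                out, omask = augment(img, mask, np.random.default_rng(seed),
                                     cfg)
                np.testing.assert_array_equal(out.pixels, img.pixels)
                np.testing.assert_array_equal(omask, mask)
                return
        pytest.fail("no identity rotation draw found")

    def test_geometric_transforms_preserve_positive_count(self):
        img, mask = self._pair()
        cfg = AugmentConfig(jitter_p=0.0, hue_p=0.0)
        for seed in range(10):
            out, omask = augment(img, mask, np.random.default_rng(seed), cfg)
            assert set(np.unique(omask)) <= {0, 1}
            assert omask.sum() == mask.sum()

    def test_colour_jitter_never_touches_mask(self):
        img, mask = self._pair()
        cfg = AugmentConfig(flip_p=0.0, jitter_p=1.0, hue_p=1.0)
        for seed in range(5):
            _, omask = augment(img, mask, np.random.default_rng(seed), cfg)
            probe = np.random.default_rng(seed)
            probe.random()           # disabled flip draw
            rot = int(probe.integers(0, 4))
            np.testing.assert_array_equal(omask, np.rot90(mask, rot))

    def test_deterministic_under_fixed_seed(self):
        img, mask = self._pair()
        a_img, a_mask = augment(img, mask, np.random.default_rng(33))
        b_img, b_mask = augment(img, mask, np.random.default_rng(33))
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_mask, b_mask)

    def test_crop_larger_than_image_rejected(self):
        img, mask = self._pair()
        with pytest.raises(ValueError, match="crop"):
            augment(img, mask, np.random.default_rng(0),
                    AugmentConfig(crop=(64, 64)))


class TestFolds:
    def test_all_kfold_schemes_partition_the_ids(self):
        ids = [f"im{i}" for i in range(40)]
        labels = cyclic_labels(ids)
        for scheme in FOLD_SCHEMES:
            k = 4 if scheme == "fold_by_week" else 5
            fa = make_folds(ids, labels, scheme, k=k, seed=1)
            assert sorted(fa.mapping) == sorted(ids)
            if scheme != "validate_week8":
                folds = set(fa.mapping.values())
                assert folds == set(range(k))
                for train, val in fa.splits():
                    assert sorted(train + val) == sorted(ids)
                    assert not set(train) & set(val)

    def test_stratified_time_balances_weeks_exactly(self):
        ids = [f"im{i}" for i in range(40)]     # 10 images per week
        fa = make_folds(ids, cyclic_labels(ids), "stratified_time", k=5,
                        seed=0)
        labels = cyclic_labels(ids)
        for f in range(5):
            fold_ids = [i for i, v in fa.mapping.items() if v == f]
            weeks = [labels[i]["week"] for i in fold_ids]
            for wk in (1, 2, 4, 8):
                assert weeks.count(wk) == 2

    def test_stratification_error_at_most_one_per_label(self):
        ids = [f"im{i}" for i in range(37)]     # deliberately uneven
        labels = cyclic_labels(ids)
        fa = make_folds(ids, labels, "stratified_condition", k=3, seed=5)
        conds = [labels[i]["condition"] for i in ids]
        for f in range(3):
            fold_ids = [i for i, v in fa.mapping.items() if v == f]
            for cond in set(conds):
                total = conds.count(cond)
                got = sum(labels[i]["condition"] == cond for i in fold_ids)
                assert abs(got - total / 3) <= 1

    def test_fold_by_week_isolates_each_week(self):
        ids = [f"im{i}" for i in range(16)]
        labels = cyclic_labels(ids)
        fa = make_folds(ids, labels, "fold_by_week", k=4, seed=0)
        for _, val in fa.splits():
            weeks = {labels[i]["week"] for i in val}
            assert len(weeks) == 1

    def test_validate_week8_split(self):
        ids = [f"im{i}" for i in range(16)]
        labels = cyclic_labels(ids)
        fa = make_folds(ids, labels, "validate_week8", seed=0)
        [(train, val)] = fa.splits()
        assert all(labels[i]["week"] == 8 for i in val)
        assert all(labels[i]["week"] != 8 for i in train)
        assert len(val) == 4

    def test_same_seed_reproduces_assignment(self):
        ids = [f"im{i}" for i in range(20)]
        a = make_folds(ids, None, "random_kfold", k=5, seed=3)
        b = make_folds(ids, None, "random_kfold", k=5, seed=3)
        assert a.mapping == b.mapping

    def test_invalid_configurations_rejected(self):
        ids = ["a", "b", "c", "d"]
        with pytest.raises(ValueError, match="k >= 2"):
            make_folds(ids, None, "random_kfold", k=1)
        with pytest.raises(ValueError, match="week"):
            make_folds(ids, None, "stratified_time", k=2)
        with pytest.raises(ValueError, match="scheme"):
            make_folds(ids, None, "leave_one_out")
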