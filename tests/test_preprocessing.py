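"""QC pairing filter and the mask/crop/resize/standardize contracts."""

import numpy as np
import pytest

from oraltriage import (
    AugmentConfig,
    ProcessedImage,
    augment,
    fit_standardizer,
    mask_crop_resize,
    qc_filter,
)
from oraltriage.preprocessing import SD_FLOOR, mask_bounding_box
from oraltriage.records import ImagePair, SiteRecord


def _site(sid, captures):
    return SiteRecord(site_id=sid, patient_id="P0", cohort="low_prevalence",
                      anatomic_label="other", referral_label="do_not_refer",
                      image_pair_ids=list(captures))


def _pair(cid, with_af=True, n=32):
    mask = np.zeros((n, n), bool)
    mask[4:-4, 4:-4] = True
    img = np.full((n, n, 3), 120, np.uint8)
    return ImagePair(capture_id=cid, wl=img, af=img.copy() if with_af else None,
                     mask=mask, lesion_mask=np.zeros((n, n), bool))


class TestQCFilter:
    def test_site_missing_af_is_removed(self):
        pairs = {"a": _pair("a", with_af=False)}
        res = qc_filter([_site("s1", ["a"])], pairs)
        assert [s.site_id for s in res.removed] == ["s1"]
        assert res.reasons["s1"] == "missing_wl_af_pair"

    def test_complete_sites_all_kept(self):
        pairs = {f"c{i}": _pair(f"c{i}") for i in range(5)}
        sites = [_site(f"s{i}", [f"c{i}"]) for i in range(5)]
        res = qc_filter(sites, pairs)
        assert res.removed == [] and len(res.kept) == 5

    def test_study_shaped_removal_counts(self):
        # 252 imaged sites, 6 without a WL+AF pair -> 246 retained
        pairs = {f"c{i}": _pair(f"c{i}", with_af=(i >= 6)) for i in range(252)}
        sites = [_site(f"s{i}", [f"c{i}"]) for i in range(252)]
        res = qc_filter(sites, pairs)
        assert len(res.kept) == 246 and len(res.removed) == 6

    def test_idempotent(self):
        pairs = {f"c{i}": _pair(f"c{i}", with_af=(i % 2 == 0)) for i in range(6)}
        sites = [_site(f"s{i}", [f"c{i}"]) for i in range(6)]
        once = qc_filter(sites, pairs)
        twice = qc_filter(once.kept, pairs)
        assert [s.site_id for s in twice.kept] == [s.site_id for s in once.kept]
        assert twice.removed == []


class TestMaskCropResize:
    def test_full_frame_mask_is_identity_shape(self):
        img = np.random.default_rng(0).integers(0, 255, (224, 224, 3)).astype(np.uint8)
        mask = np.ones((224, 224), bool)
        out = mask_crop_resize(img, mask, 224)
        assert np.allclose(out.tensor, img, atol=1e-6)

    def test_crop_box_coordinates(self):
        img = np.random.default_rng(1).integers(0, 255, (256, 256, 3)).astype(np.uint8)
        mask = np.zeros((256, 256), bool)
        mask[10:110, 20:120] = True
        assert mask_bounding_box(mask) == (10, 110, 20, 120)
        out = mask_crop_resize(img, mask, 224)
        # independently crop-then-resize the hand-identified 100x100 box
        from skimage.transform import resize

        expected = resize(img[10:110, 20:120].astype(float), (224, 224), order=1,
                          mode="edge", anti_aliasing=False, preserve_range=True)
        assert np.allclose(out.tensor, expected, atol=1e-4)

    def test_output_always_224(self):
        rng = np.random.default_rng(2)
        for n in (64, 100, 300):
            img = rng.integers(0, 255, (n, n, 3)).astype(np.uint8)
            mask = np.zeros((n, n), bool)
            mask[n // 4 : n // 2, n // 3 : 2 * n // 3] = True
            assert mask_crop_resize(img, mask).tensor.shape == (224, 224, 3)

    def test_no_information_leaks_from_outside_mask(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 255, (80, 80, 3)).astype(np.uint8)
        mask = np.zeros((80, 80), bool)
        mask[20:60, 10:70] = True
        pre_zeroed = img * mask[..., None]
        a = mask_crop_resize(img, mask, 64)
        b = mask_crop_resize(pre_zeroed, mask, 64)
        assert np.array_equal(a.tensor, b.tensor)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            mask_crop_resize(np.zeros((32, 32, 3)), np.zeros((32, 32), bool))


class TestStandardizer:
    def test_two_pixel_population_stats(self):
        imgs = [
            ProcessedImage(tensor=np.full((1, 1, 3), v, np.float32), modality="WL")
            for v in (0.0, 10.0)
        ]
        std = fit_standardizer(imgs)
        assert np.allclose(std.mean["WL"], 5.0)
        assert np.allclose(std.sd["WL"], 5.0)  # population, not sample, sd

    def test_constant_images_floor_sd(self):
        imgs = [ProcessedImage(tensor=np.full((4, 4, 3), 50.0, np.float32), modality="AF")]
        std = fit_standardizer(imgs)
        assert np.allclose(std.mean["AF"], 50.0)
        assert np.allclose(std.sd["AF"], SD_FLOOR)

    def test_self_consistency_on_fitting_set(self):
        rng = np.random.default_rng(4)
        imgs = [
            ProcessedImage(tensor=rng.normal(100, 20, (16, 16, 3)).astype(np.float32),
                           modality="WL")
            for _ in range(10)
        ]
        std = fit_standardizer(imgs)
        pixels = np.concatenate(
            [std.apply(im).tensor.reshape(-1, 3) for im in imgs]
        )
        assert np.all(np.abs(pixels.mean(axis=0)) < 1e-4)
        assert np.all(np.abs(pixels.std(axis=0) - 1.0) < 1e-3)

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer([])

    def test_json_round_trip(self, tmp_path):
        imgs = [ProcessedImage(tensor=np.ones((2, 2, 3), np.float32), modality="WL")]
        std = fit_standardizer(imgs, fitted_on="demo")
        std.to_json(tmp_path / "std.json")
        from oraltriage import Standardizer

        back = Standardizer.from_json(tmp_path / "std.json")
        assert back.fitted_on == "demo"
        assert np.allclose(back.mean["WL"], std.mean["WL"])


class TestAugment:
    def test_disabled_is_identity(self, rng):
        img = ProcessedImage(tensor=rng.normal(size=(8, 8, 3)).astype(np.float32),
                             modality="WL")
        out = augment(img, rng, AugmentConfig(enabled=False))
        assert np.array_equal(out.tensor, img.tensor)

    def test_seeded_reproducibility(self):
        img = ProcessedImage(tensor=np.random.default_rng(0).normal(size=(8, 8, 3))
                             .astype(np.float32), modality="WL")
        cfg = AugmentConfig(enabled=True)
        a = augment(img, 42, cfg)
        b = augment(img, 42, cfg)
        assert np.array_equal(a.tensor, b.tensor)

    def test_forced_flip_is_involution(self):
        img = ProcessedImage(tensor=np.arange(48, dtype=np.float32).reshape(4, 4, 3),
                             modality="WL")
        cfg = AugmentConfig(enabled=True, flip_prob=1.0, max_rotation_deg=0.0)
        twice = augment(augment(img, 0, cfg), 1, cfg)
        assert np.allclose(twice.tensor, img.tensor)
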