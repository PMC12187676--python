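"""Loading/validation, z-scoring, augmentation label safety, case-level split."""

import numpy as np
import pytest
from PIL import Image

from hasaseg.config import AugmentConfig
from hasaseg.data_io import (Sample, augment, load_dataset, load_manifest,
                             split, zscore)


class TestZscore:
    def test_definition_on_small_vector(self):
        z = zscore(np.array([1.0, 2.0, 3.0, 4.0]))
        assert abs(z.mean()) < 1e-12 and abs(z.std() - 1.0) < 1e-12

    def test_constant_image_maps_to_zeros(self):
        np.testing.assert_array_equal(zscore(np.full((4, 4), 7.0)), 0.0)

    def test_idempotent(self, rng):
        x = rng.normal(3.0, 5.0, size=(16, 16))
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-6)

    def test_contract_on_many_random_images(self, rng):
        for _ in range(100):
            z = zscore(rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                                  size=(12, 12)))
            assert abs(z.mean()) < 1e-4 and abs(z.std() - 1.0) < 1e-4


def _write_pair(root, stem, image, mask):
    (root / "images").mkdir(exist_ok=True, parents=True)
    (root / "masks").mkdir(exist_ok=True, parents=True)
    Image.fromarray(image.astype(np.uint16)).save(root / "images" / f"{stem}.png")
    Image.fromarray(mask.astype(np.uint8)).save(root / "masks" / f"{stem}.png")


class TestLoadDataset:
    def test_pairs_by_stem(self, tmp_path, rng):
        for i in range(3):
            _write_pair(tmp_path, f"s{i}", rng.integers(0, 1000, (8, 8)),
                        rng.integers(0, 11, (8, 8)))
        samples = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert len(samples) == 3
        assert all(abs(s.image.mean()) < 1e-6 for s in samples)

    def test_mask_value_out_of_range_names_file(self, tmp_path, rng):
        mask = np.zeros((8, 8)); mask[0, 0] = 11
        _write_pair(tmp_path, "bad", rng.integers(0, 100, (8, 8)), mask)
        with pytest.raises(ValueError, match="bad"):
            load_dataset(tmp_path / "images", tmp_path / "masks")

    def test_size_mismatch_rejected(self, tmp_path, rng):
        (tmp_path / "images").mkdir(); (tmp_path / "masks").mkdir()
        Image.fromarray(np.zeros((8, 8), np.uint16)).save(
            tmp_path / "images" / "a.png")
        Image.fromarray(np.zeros((8, 9), np.uint8)).save(
            tmp_path / "masks" / "a.png")
        with pytest.raises(ValueError, match="mismatch"):
            load_dataset(tmp_path / "images", tmp_path / "masks")

    def test_unmatched_stems_reported(self, tmp_path, rng):
        _write_pair(tmp_path, "a", np.zeros((4, 4)), np.zeros((4, 4)))
        Image.fromarray(np.zeros((4, 4), np.uint16)).save(
            tmp_path / "images" / "orphan.png")
        with pytest.raises(ValueError, match="orphan"):
            load_dataset(tmp_path / "images", tmp_path / "masks")

    def test_nifti_volume_expands_to_slices(self, tmp_path, rng):
        import nibabel as nib
        vol = rng.integers(0, 500, size=(8, 8, 5)).astype(np.int16)
        msk = rng.integers(0, 11, size=(8, 8, 5)).astype(np.uint8)
        (tmp_path / "images").mkdir(); (tmp_path / "masks").mkdir()
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "images" / "case1.nii")
        nib.save(nib.Nifti1Image(msk, np.eye(4)), tmp_path / "masks" / "case1.nii")
        samples = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert len(samples) == 5
        assert samples[0].id == "case1_s000"
        assert all(s.case_id == "case1" for s in samples)


class TestAugment:
    def _sample(self, rng, size=32):
        mask = rng.integers(0, 11, size=(size, size)).astype(np.uint8)
        return Sample(rng.normal(size=(1, size, size)), mask, "s")

    def test_zero_probability_is_identity(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(probability=0.0)
        out = augment(s, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_deterministic_given_seed(self, rng):
        s = self._sample(rng)
        cfg = AugmentConfig(probability=1.0)
        a = augment(s, cfg, np.random.default_rng(9))
        b = augment(s, cfg, np.random.default_rng(9))
        c = augment(s, cfg, np.random.default_rng(10))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert not np.array_equal(a.image, c.image)

    def test_labels_stay_in_codebook_over_many_draws(self, rng):
        cfg = AugmentConfig(probability=1.0)
        s = self._sample(rng)
        for i in range(100):
            out = augment(s, cfg, np.random.default_rng(i))
            assert set(np.unique(out.mask)) <= set(range(11))
            assert out.mask.dtype == np.uint8

    def test_constant_mask_survives_geometry(self, rng):
        s = Sample(rng.normal(size=(1, 24, 24)),
                   np.full((24, 24), 3, np.uint8), "s")
        cfg = AugmentConfig(probability=1.0, gauss_noise_sigma=0.0, brightness=0.0)
        out = augment(s, cfg, np.random.default_rng(4))
        # rotation fill introduces background at corners; interior stays 3
        assert set(np.unique(out.mask)) <= {0, 3}
        assert out.mask[12, 12] == 3


class TestSplit:
    def _cases(self, n_cases, per_case=2):
        return [Sample(np.zeros((1, 4, 4)), np.zeros((4, 4), np.uint8),
                       f"c{c}_s{s}", case_id=f"c{c}")
                for c in range(n_cases) for s in range(per_case)]

    def test_ten_cases_split_8_1_1(self):
        tr, va, te = split(self._cases(10), seed=0)
        cases = lambda part: {s.case_id for s in part}
        assert (len(cases(tr)), len(cases(va)), len(cases(te))) == (8, 1, 1)

    def test_partition_is_disjoint_and_exhaustive(self):
        samples = self._cases(12, per_case=3)
        tr, va, te = split(samples, seed=1)
        ids = [s.id for part in (tr, va, te) for s in part]
        assert sorted(ids) == sorted(s.id for s in samples)
        assert not ({s.case_id for s in tr} & {s.case_id for s in va})
        assert not ({s.case_id for s in tr} & {s.case_id for s in te})

    def test_cases_never_straddle_splits(self):
        tr, va, te = split(self._cases(7, per_case=4), seed=3)
        for part in (tr, va, te):
            for cid in {s.case_id for s in part}:
                assert sum(1 for s in part if s.case_id == cid) == 4

    def test_reproducible_by_seed(self):
        samples = self._cases(9)
        a = split(samples, seed=5)
        b = split(samples, seed=5)
        assert [[s.id for s in part] for part in a] == \
               [[s.id for s in part] for part in b]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split(self._cases(1, per_case=2))


class TestManifest:
    def test_roundtrip_through_generated_dataset(self, tmp_path):
        from hasaseg.synthetic import PhantomSpec, generate_dataset
        manifest = generate_dataset(PhantomSpec(size=(32, 32)), 4, tmp_path, seed=0)
        samples = load_manifest(manifest)
        assert len(samples) == 4
        assert all(s.mask.max() <= 10 for s in samples)
        assert all(abs(s.image.mean()) < 1e-6 for s in samples)
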