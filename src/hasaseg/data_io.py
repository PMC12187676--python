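"""Dataset loading, z-score normalization, online augmentation, splitting.

Images are grayscale PNG/TIFF slices (8/16-bit) or NIfTI volumes sliced
along a chosen axis; masks are integer label maps with values 0..K-1
(default K = 11).  Every image is z-scored per slice (mean 0, std 1) at load
time.  Augmentation is applied online: rotation and elastic deformation hit
image and mask identically (nearest-neighbor resampling keeps labels
integral), Gaussian noise and brightness shifts hit the image only.  The
train/validation/test split is 8:1:1 at the case level so slices of one
acquisition never straddle splits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import AugmentConfig

__all__ = ["Sample", "zscore", "load_image", "load_mask", "load_dataset",
           "load_manifest", "augment", "split", "NUM_CLASSES", "CLASS_NAMES"]

NUM_CLASSES = 11
CLASS_NAMES = [
    "background", "skin", "femur", "tibia", "lateral_meniscus",
    "medial_meniscus", "patella", "patellar_ligament", "fibula",
    "posterior_cruciate_ligament", "anterior_cruciate_ligament",
]


@dataclass
class Sample:
    """One z-scored slice with its label map."""
    image: np.ndarray          # float, shape (1, H, W)
    mask: np.ndarray           # uint8, shape (H, W), values in 0..K-1
    id: str
    case_id: str | None = None


def zscore(image: np.ndarray) -> np.ndarray:
    """Per-image standardization; constant images map to all zeros."""
    x = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains NaN or Inf")
    std = x.std()
    return (x - x.mean()) / max(std, 1e-8)


def _read_gray(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("F")
        return np.asarray(im, dtype=np.float64)


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF into a float array (no normalization)."""
    return _read_gray(Path(path))


def load_mask(path: str | Path, num_classes: int = NUM_CLASSES) -> np.ndarray:
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: mask must be single-channel")
    if arr.max() >= num_classes:
        raise ValueError(
            f"{path.name}: mask value {int(arr.max())} exceeds the maximum "
            f"class index {num_classes - 1}")
    return arr.astype(np.uint8)


def _nifti_slices(path: Path, axis: int) -> list[np.ndarray]:
    import nibabel as nib
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D NIfTI volume")
    return [np.take(vol, i, axis=axis) for i in range(vol.shape[axis])]

_IMG_EXT = {".png", ".tif", ".tiff"}
_NII_EXT = {".nii", ".gz"}


def _is_nifti(p: Path) -> bool:
    return p.suffix == ".nii" or p.name.endswith(".nii.gz")


def _stem(p: Path) -> str:
    return p.name[:-7] if p.name.endswith(".nii.gz") else p.stem


def load_dataset(images_dir: str | Path, masks_dir: str | Path,
                 num_classes: int = NUM_CLASSES, slice_axis: int = 2,
                 normalize: bool = True) -> list[Sample]:
    """Pair images and masks by filename stem and validate them.

    NIfTI volumes expand into per-slice samples with ids ``<stem>_s<i>`` and
    ``case_id = <stem>``.  Unmatched files raise with the offending names.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    img_files = {_stem(p): p for p in sorted(images_dir.iterdir())
                 if p.suffix.lower() in _IMG_EXT or _is_nifti(p)}
    mask_files = {_stem(p): p for p in sorted(masks_dir.iterdir())
                  if p.suffix.lower() in _IMG_EXT or _is_nifti(p)}
    unmatched = sorted(set(img_files) ^ set(mask_files))
    if unmatched:
        raise ValueError(f"unmatched image/mask stems: {unmatched}")

    samples: list[Sample] = []
    for stem in sorted(img_files):
        ipath, mpath = img_files[stem], mask_files[stem]
        if _is_nifti(ipath):
            imgs = _nifti_slices(ipath, slice_axis)
            msks = _nifti_slices(mpath, slice_axis)
            if len(imgs) != len(msks):
                raise ValueError(f"{stem}: image/mask slice counts differ")
            for i, (img, msk) in enumerate(zip(imgs, msks)):
                samples.append(_make_sample(img, msk, f"{stem}_s{i:03d}", stem,
                                            num_classes, normalize))
        else:
            img = _read_gray(ipath)
            msk = load_mask(mpath, num_classes)
            samples.append(_make_sample(img, msk, stem, None, num_classes,
                                        normalize, mpath.name))
    return samples


def _make_sample(img: np.ndarray, msk: np.ndarray, sid: str, case_id: str | None,
                 num_classes: int, normalize: bool, name: str = "") -> Sample:
    msk = np.asarray(msk)
    if msk.max() >= num_classes:
        raise ValueError(f"{name or sid}: mask value {int(msk.max())} exceeds "
                         f"{num_classes - 1}")
    if img.shape != msk.shape:
        raise ValueError(f"{name or sid}: image {img.shape} vs mask {msk.shape} "
                         "size mismatch")
    x = zscore(img) if normalize else np.asarray(img, dtype=np.float64)
    return Sample(image=x[None], mask=msk.astype(np.uint8), id=sid, case_id=case_id)


def load_manifest(manifest_csv: str | Path, num_classes: int = NUM_CLASSES,
                  normalize: bool = True) -> list[Sample]:
    """Load samples listed in a manifest CSV (id, image_path, mask_path, case_id).

    Relative paths resolve against the manifest's directory.
    """
    manifest_csv = Path(manifest_csv)
    root = manifest_csv.parent
    samples = []
    with open(manifest_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            img = _read_gray(root / row["image_path"])
            msk = load_mask(root / row["mask_path"], num_classes)
            samples.append(_make_sample(img, msk, row["id"],
                                        row.get("case_id") or None,
                                        num_classes, normalize))
    return samples


# -- augmentation ---------------------------------------------------------

def _elastic_fields(shape, alpha, sigma, rng):
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return yy + dy, xx + dx


def augment(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator) -> Sample:
    """One random augmentation draw; deterministic given the rng state."""
    img = sample.image[0]
    mask = sample.mask

    if rng.random() < cfg.probability and cfg.rotation_deg > 0:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant",
                             cval=0.0)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant",
                              cval=0)

    if rng.random() < cfg.probability and cfg.elastic_alpha > 0:
        coords = _elastic_fields(img.shape, cfg.elastic_alpha, cfg.elastic_sigma, rng)
        img = ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant", cval=0)

    if rng.random() < cfg.probability and cfg.gauss_noise_sigma > 0:
        scale = cfg.gauss_noise_sigma * max(img.std(), 1e-8)
        img = img + rng.normal(0.0, scale, img.shape)

    if rng.random() < cfg.probability and cfg.brightness > 0:
        img = img + rng.uniform(-cfg.brightness, cfg.brightness) * max(img.std(), 1.0)

    return replace(sample, image=img[None].astype(np.float64),
                   mask=mask.astype(np.uint8))


# -- splitting ------------------------------------------------------------

def split(samples: list[Sample], ratios: tuple[float, float, float] = (8, 1, 1),
          seed: int = 0) -> tuple[list[Sample], list[Sample], list[Sample]]:
    """Case-level random 8:1:1 partition (disjoint, exhaustive, seeded).

    Samples without a ``case_id`` count as singleton cases.  Each split
    receives at least one case.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to split")
    groups: dict[str, list[Sample]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(s.case_id or f"__solo_{i}", []).append(s)
    case_ids = sorted(groups)
    if len(case_ids) < 3:
        raise ValueError("need at least 3 cases to split")
    rng = np.random.default_rng(seed)
    rng.shuffle(case_ids)
    total = sum(ratios)
    n = len(case_ids)
    n_train = max(1, round(n * ratios[0] / total))
    n_val = max(1, round(n * ratios[1] / total))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    parts = (case_ids[:n_train],
             case_ids[n_train:n_train + n_val],
             case_ids[n_train + n_val:])
    return tuple([s for cid in part for s in groups[cid]] for part in parts)
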