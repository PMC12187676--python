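"""Synthetic knee-phantom generator.

Real sagittal knee MRI brings three statistical pathologies that make
multi-class segmentation hard: a heavily dominant background, large smooth
structures (skin, femur, tibia) next to small/thin low-frequency ones
(menisci, cruciate ligaments, fibula) present only in a fraction of slices,
and low-contrast blurred boundaries.  The phantom reproduces exactly those
statistics with parametric primitives — ellipses for bones, an annulus for
skin, crescents for menisci, oriented thin bands for ligaments — laid out in
an anatomically inspired sagittal arrangement.  It is a statistical
stand-in, not an anatomical atlas: it exists so that imbalance-sensitive
losses, small-structure attention and the ablation harness can be exercised
end-to-end without any external data.

Intensities are per-structure means plus texture noise, Gaussian-blurred to
soften boundaries (the label map stays crisp), then perturbed by global
noise and a per-image intensity shift/gain.  Later-painted structures
occlude earlier ones in the fixed order bones < skin < small structures.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_io import CLASS_NAMES, NUM_CLASSES, Sample, zscore

__all__ = ["PhantomSpec", "generate_phantom", "generate_samples",
           "generate_dataset", "render_phantom"]

# per-structure appearance probability, classes 1..10
_DEFAULT_FREQS = (1.0, 1.0, 1.0, 0.5, 0.5, 0.4, 0.4, 0.4, 0.25, 0.25)

# mean intensity per class 0..10 (arbitrary units; background darkest)
_INTENSITY = (0.20, 0.70, 0.82, 0.80, 0.42, 0.44, 0.76, 0.52, 0.74, 0.46, 0.48)


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    ``class_freqs[c-1]`` is the probability that structure ``c`` (1..10)
    appears in a slice; skin and bones are near-always present, menisci
    about half the time, cruciate ligaments in a quarter of slices.
    ``boundary_blur_sigma`` (pixels) controls boundary softness,
    ``noise_sigma`` the global additive noise, ``texture_sigma`` the
    within-structure texture, ``intensity_shift`` the per-image brightness
    wobble.  Geometry jitter scales shape/position diversity.
    """
    size: tuple[int, int] = (96, 96)
    class_freqs: tuple[float, ...] = _DEFAULT_FREQS
    intensities: tuple[float, ...] = _INTENSITY
    boundary_blur_sigma: float = 1.2
    noise_sigma: float = 0.03
    texture_sigma: float = 0.02
    intensity_shift: float = 0.05
    geometry_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.class_freqs) != NUM_CLASSES - 1:
            raise ValueError(f"class_freqs needs {NUM_CLASSES - 1} entries")
        if any(not 0.0 <= f <= 1.0 for f in self.class_freqs):
            raise ValueError("class_freqs must lie in [0, 1]")
        if min(self.size) < 16:
            raise ValueError("phantom size too small")


def _rot(yy, xx, cy, cx, angle):
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    return c * dy - s * dx, s * dy + c * dx


def _ellipse(yy, xx, cy, cx, ay, ax, angle=0.0):
    u, v = _rot(yy, xx, cy, cx, angle)
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def _band(yy, xx, cy, cx, angle, length, width):
    u, v = _rot(yy, xx, cy, cx, angle)
    return (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)


def _structures(rng: np.random.Generator, jitter: float):
    """Per-class boolean-mask painters on a normalized [0,1]^2 grid."""
    j = jitter

    def u(lo, hi):
        return rng.uniform(lo, hi)

    # draw all jitters up front so rng consumption is independent of presence
    p = {
        "skin": (u(-.01, .01) * j, u(-.01, .01) * j, 0.47 + u(-.015, .015) * j,
                 0.46 + u(-.015, .015) * j, 0.035 + u(-.008, .012) * j),
        "femur": (0.30 + u(-.03, .03) * j, 0.52 + u(-.04, .04) * j,
                  0.20 + u(-.03, .03) * j, 0.19 + u(-.03, .03) * j, u(-.3, .3) * j),
        "tibia": (0.74 + u(-.03, .03) * j, 0.55 + u(-.04, .04) * j,
                  0.16 + u(-.02, .02) * j, 0.20 + u(-.03, .03) * j, u(-.3, .3) * j),
        "lmen": (0.52 + u(-.02, .02) * j, 0.40 + u(-.03, .03) * j,
                 0.050 + u(-.008, .012) * j, 0.065 + u(-.01, .015) * j),
        "mmen": (0.52 + u(-.02, .02) * j, 0.66 + u(-.03, .03) * j,
                 0.050 + u(-.008, .012) * j, 0.065 + u(-.01, .015) * j),
        "patella": (0.36 + u(-.02, .02) * j, 0.14 + u(-.02, .02) * j,
                    0.070 + u(-.01, .01) * j, 0.036 + u(-.006, .008) * j,
                    u(-.2, .2) * j),
        "patlig": (0.55 + u(-.02, .02) * j, 0.15 + u(-.02, .02) * j,
                   1.40 + u(-.15, .15) * j, 0.30 + u(-.04, .04) * j,
                   0.030 + u(-.006, .008) * j),
        "fibula": (0.85 + u(-.02, .02) * j, 0.82 + u(-.03, .03) * j,
                   0.060 + u(-.01, .01) * j, 0.045 + u(-.008, .008) * j,
                   u(-.2, .2) * j),
        "pcl": (0.55 + u(-.02, .02) * j, 0.60 + u(-.03, .03) * j,
                0.80 + u(-.15, .15) * j, 0.18 + u(-.03, .03) * j,
                0.028 + u(-.005, .007) * j),
        "acl": (0.52 + u(-.02, .02) * j, 0.48 + u(-.03, .03) * j,
                -0.70 + u(-.15, .15) * j, 0.20 + u(-.03, .03) * j,
                0.024 + u(-.004, .006) * j),
    }

    def skin(yy, xx):
        dy, dx, ay, ax, t = p["skin"]
        r2 = ((yy - 0.5 - dy) / ay) ** 2 + ((xx - 0.5 - dx) / ax) ** 2
        return ((1.0 - t / min(ay, ax)) ** 2 <= r2) & (r2 <= 1.0)

    def crescent(key):
        cy, cx, ay, ax = p[key]

        def painter(yy, xx):
            outer = _ellipse(yy, xx, cy, cx, ay, ax)
            inner = _ellipse(yy, xx, cy - 0.45 * ay, cx, ay, ax)
            return outer & ~inner
        return painter

    def ellipse(key):
        cy, cx, ay, ax, ang = p[key]
        return lambda yy, xx: _ellipse(yy, xx, cy, cx, ay, ax, ang)

    def band(key):
        cy, cx, ang, length, width = p[key]
        return lambda yy, xx: _band(yy, xx, cy, cx, ang, length, width)

    # paint order: bones < skin < small structures
    return [
        (2, ellipse("femur")),
        (3, ellipse("tibia")),
        (1, skin),
        (6, ellipse("patella")),
        (8, ellipse("fibula")),
        (4, crescent("lmen")),
        (5, crescent("mmen")),
        (7, band("patlig")),
        (9, band("pcl")),
        (10, band("acl")),
    ]


def render_phantom(spec: PhantomSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Raw intensity image and crisp label map for one phantom slice."""
    h, w = spec.size
    yy, xx = np.meshgrid((np.arange(h) + 0.5) / h, (np.arange(w) + 0.5) / w,
                         indexing="ij")
    present = rng.random(NUM_CLASSES - 1) < np.asarray(spec.class_freqs)
    painters = _structures(rng, spec.geometry_jitter)

    mask = np.zeros((h, w), dtype=np.uint8)
    for cls, painter in painters:
        if present[cls - 1]:
            mask[painter(yy, xx)] = cls

    img = np.asarray(spec.intensities, dtype=np.float64)[mask]
    if spec.texture_sigma > 0:
        img = img + rng.normal(0.0, spec.texture_sigma, img.shape)
    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    shift = rng.uniform(-spec.intensity_shift, spec.intensity_shift)
    gain = rng.uniform(0.92, 1.08)
    img = gain * img + shift
    return img, mask


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator,
                     sample_id: str = "phantom", case_id: str | None = None
                     ) -> Sample:
    """One z-scored phantom :class:`~hasaseg.data_io.Sample`."""
    img, mask = render_phantom(spec, rng)
    return Sample(image=zscore(img)[None], mask=mask, id=sample_id,
                  case_id=case_id)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_samples(spec: PhantomSpec, n: int, seed: int = 0,
                     slices_per_case: int = 6) -> list[Sample]:
    """``n`` in-memory samples with case ids grouping consecutive slices."""
    return [generate_phantom(spec, rng, sample_id=f"phantom_{i:04d}",
                             case_id=f"case_{i // slices_per_case:03d}")
            for i, rng in enumerate(_child_rngs(seed, n))]


def generate_dataset(spec: PhantomSpec, n: int, out_dir: str | Path,
                     seed: int = 0, slices_per_case: int = 6) -> Path:
    """Write ``n`` image/mask PNG pairs plus a manifest CSV; returns its path.

    Images are stored as 16-bit grayscale PNG (intensities mapped linearly
    from [-0.2, 1.4]); masks as 8-bit indexed PNG.  Per-sample seeds derive
    deterministically from the master seed, so two runs with the same seed
    produce byte-identical files.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rng in enumerate(_child_rngs(seed, n)):
        img, mask = render_phantom(spec, rng)
        sid = f"phantom_{i:04d}"
        arr = np.clip((img + 0.2) / 1.6, 0.0, 1.0)
        Image.fromarray((arr * 65535).astype(np.uint16)).save(
            out_dir / "images" / f"{sid}.png")
        Image.fromarray(mask).save(out_dir / "masks" / f"{sid}.png")
        rows.append({"id": sid, "image_path": f"images/{sid}.png",
                     "mask_path": f"masks/{sid}.png",
                     "case_id": f"case_{i // slices_per_case:03d}"})
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "image_path", "mask_path",
                                                "case_id"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def dataset_hash(out_dir: str | Path) -> str:
    """SHA-256 over all PNG bytes (sorted paths) — a determinism fingerprint."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).rglob("*.png")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()
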