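"""Synthetic fixtures emulating scarce annotated MR data, plus the data-preparation
pipeline (slicing, ROI cropping, augmentation, expansion, splitting).

Two generators are provided:

* **phantoms** — grayscale head-phantom-like images: nested, randomly posed
  elliptical shells with per-shell intensity levels and additive Gaussian
  noise.  They stand in for simulated T1-weighted brain slices (synthetic;
  no external data is downloaded).
* **lesion patches** — a two-class (malignant/benign) patch set with the
  study's class imbalance (75 malignant : 250 benign by default).  Benign
  lesions are smooth round hypointense blobs; malignant lesions gain
  boundary irregularity and internal speckle as the ``separability`` knob
  rises from 0 (classes identically distributed) to 1.

Every operation is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse
from skimage.transform import AffineTransform, warp

__all__ = [
    "PhantomSpec", "LesionRecord", "AugmentationConfig",
    "generate_phantoms", "generate_lesion_dataset", "slice_volume",
    "roi_crop", "augment", "expand_with_originals", "split_dataset",
    "write_image_dir", "load_image_dir",
]


@dataclass
class PhantomSpec:
    image_size: int = 64
    n_shells: int = 3
    intensity_levels: tuple = (200, 130, 80)   # outer -> inner, 0-255
    noise_sd: float = 8.0
    deformation: float = 0.08                  # relative jitter of shell axes
    seed: int = 0

    def __post_init__(self):
        if self.n_shells < 1:
            raise ValueError("need at least one shell")
        if len(self.intensity_levels) < self.n_shells:
            raise ValueError("one intensity level per shell is required")
        levels = np.asarray(self.intensity_levels, float)
        if levels.min() < 0 or levels.max() > 255:
            raise ValueError("intensity levels must lie in [0, 255]")
        if self.noise_sd < 0 or self.deformation < 0:
            raise ValueError("noise_sd and deformation must be nonnegative")


@dataclass
class LesionRecord:
    """One lesion patch: image (or path), 0-based (row, col) center, label."""

    image: np.ndarray | None
    center: tuple
    label: str
    path: str | None = None

    def __post_init__(self):
        if self.label not in ("malignant", "benign"):
            raise ValueError(f"label must be 'malignant' or 'benign', got {self.label!r}")
        if self.image is not None:
            r, c = self.center
            h, w = self.image.shape[:2]
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"lesion center {self.center} outside image of shape {(h, w)}")


@dataclass
class AugmentationConfig:
    rotation_deg: float = 15.0
    translation_px: float = 3.0
    scale_range: tuple = (0.9, 1.1)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.rotation_deg < 0 or self.translation_px < 0 or self.noise_sd < 0:
            raise ValueError("augmentation ranges must be nonnegative")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < lo <= hi")

    @property
    def is_identity(self) -> bool:
        lo, hi = self.scale_range
        return (self.rotation_deg == 0 and self.translation_px == 0
                and lo == 1.0 and hi == 1.0 and self.noise_sd == 0)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_phantoms(n: int, spec: PhantomSpec | None = None,
                      out_dir: str | Path | None = None):
    """Generate ``n`` nested-shell phantom images (uint8, file range).

    Returns ``(images, manifest)`` with images ``(n, size, size)`` and a
    manifest DataFrame (path, center_row, center_col, label).  With
    ``out_dir`` the images and ``manifest.csv`` are also written to disk.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    images = np.zeros((n, s, s), dtype=np.uint8)
    for k in range(n):
        img = np.zeros((s, s), dtype=float)
        cy = s / 2 + rng.uniform(-0.04, 0.04) * s
        cx = s / 2 + rng.uniform(-0.04, 0.04) * s
        a0 = s * rng.uniform(0.38, 0.44)         # semi-major axis of the outer shell
        b0 = a0 * rng.uniform(0.75, 0.95)
        theta = rng.uniform(0, np.pi)
        for shell in range(spec.n_shells):
            shrink = 1.0 - shell / (spec.n_shells + 0.5)
            jit = 1.0 + rng.uniform(-spec.deformation, spec.deformation)
            rr, cc = ellipse(cy, cx, max(a0 * shrink * jit, 1.5),
                             max(b0 * shrink * jit, 1.5),
                             shape=(s, s), rotation=theta)
            img[rr, cc] = spec.intensity_levels[shell]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        images[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    manifest = pd.DataFrame({
        "path": [f"phantom_{k:05d}.png" for k in range(n)],
        "center_row": s // 2, "center_col": s // 2,
        "label": "phantom",
    })
    if out_dir is not None:
        write_image_dir(images, manifest, out_dir)
    return images, manifest


def _lesion_boundary(radius, irregularity, n_lobes, phase, theta):
    return radius * (1.0 + irregularity * np.cos(n_lobes * theta + phase))


def generate_lesion_dataset(n_malignant: int = 75, n_benign: int = 250,
                            image_size: int = 64, seed: int = 0,
                            separability: float = 1.0) -> list[LesionRecord]:
    """Two-class lesion patch set with a 75:250 class imbalance, the kind of
    skew seen in prostate mp-MRI lesion corpora.

    ``separability`` scales every malignant-vs-benign difference; at 0 the
    two classes are drawn from the same distribution.
    """
    if n_malignant < 1 or n_benign < 1:
        raise ValueError("class counts must be >= 1")
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s]
    records: list[LesionRecord] = []
    labels = ["malignant"] * n_malignant + ["benign"] * n_benign
    for label in labels:
        mal = label == "malignant"
        # smooth tissue background
        bg = rng.normal(110.0, 12.0, size=(s, s))
        bg = _smooth(bg)
        margin = s // 4
        r0 = rng.integers(margin, s - margin)
        c0 = rng.integers(margin, s - margin)
        radius = rng.uniform(5.0, 7.0) + (2.0 * separability if mal else 0.0)
        irregularity = (0.35 * separability) if mal else 0.0
        n_lobes = rng.integers(4, 7)
        phase = rng.uniform(0, 2 * np.pi)
        theta = np.arctan2(yy - r0, xx - c0)
        rad = np.hypot(yy - r0, xx - c0)
        boundary = _lesion_boundary(radius, irregularity, n_lobes, phase, theta)
        mask = rad <= boundary
        img = bg.copy()
        img[mask] -= 45.0
        if mal and separability > 0:
            img[mask] += rng.normal(0.0, 22.0 * separability, size=int(mask.sum()))
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        records.append(LesionRecord(image=img, center=(int(r0), int(c0)), label=label))
    return records


def _smooth(img: np.ndarray) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(img, sigma=2.0)


# ---------------------------------------------------------------------------
# pipeline operators
# ---------------------------------------------------------------------------

def slice_volume(volume) -> list[np.ndarray]:
    """Split a 3-D array into its 2-D slices along axis 0, order preserved.

    A path to a NIfTI file is also accepted; the volume is then sliced
    along its third (slice) axis.
    """
    if isinstance(volume, (str, Path)):
        import nibabel as nib
        data = np.asanyarray(nib.load(str(volume)).dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
        volume = np.moveaxis(data, 2, 0)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    if volume.shape[0] == 0:
        raise ValueError("volume has no slices")
    return [volume[i] for i in range(volume.shape[0])]


def roi_crop(record: LesionRecord, side: int = 35) -> np.ndarray:
    """Fixed ``side x side`` patch centered on the lesion (reflect-padded).

    The lesion center lands on patch pixel ``(side // 2, side // 2)``.
    """
    img = record.image
    if img is None:
        raise ValueError("record carries no image array")
    if side > min(img.shape[:2]):
        raise ValueError(f"side {side} exceeds image dimensions {img.shape[:2]}")
    half = side // 2
    padded = np.pad(img, ((side, side), (side, side)), mode="reflect")
    r, c = record.center
    r0, c0 = r + side - half, c + side - half
    return padded[r0:r0 + side, c0:c0 + side].copy()


def augment(img: np.ndarray, config: AugmentationConfig | None = None,
            k: int = 1, rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """``k`` independent randomized rigid+noise transforms of one image.

    Rotation, isotropic scaling about the image center, translation, and
    additive Gaussian noise; reflect boundary handling, bilinear sampling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    config = config or AugmentationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    img_f = np.asarray(img, dtype=float)
    out = []
    for _ in range(k):
        if config.is_identity:
            out.append(np.asarray(img).copy())
            continue
        angle = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
        scale = rng.uniform(*config.scale_range)
        tr, tc = rng.uniform(-config.translation_px, config.translation_px, size=2)
        center = np.array(img_f.shape[::-1]) / 2.0 - 0.5
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=angle, scale=scale)
              + AffineTransform(translation=center + (tc, tr)))
        warped = warp(img_f, tf.inverse, order=1, mode="reflect", preserve_range=True)
        if config.noise_sd > 0:
            warped = warped + rng.normal(0.0, config.noise_sd, size=warped.shape)
        out.append(np.clip(np.rint(warped), 0, 255).astype(np.uint8))
    return out


def expand_with_originals(images, config: AugmentationConfig | None = None,
                          k: int = 20, seed: int = 0) -> np.ndarray:
    """Expand a set to ``n * (k + 1)`` images: originals first, then ``k``
    augmented copies per original (grouped by source image)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    images = np.asarray(images)
    if k == 0:
        return images.copy()
    config = config or AugmentationConfig()
    rng = np.random.default_rng(seed)
    augmented = [a for img in images for a in augment(img, config, k=k, rng=rng)]
    return np.concatenate([images, np.stack(augmented)], axis=0)


def split_dataset(records: list, train_fraction: float = 0.8, seed: int = 0,
                  stratified: bool = True):
    """Random train/test split; stratified keeps per-class proportions
    (train size rounded to nearest per class).  Returns ``(train, test)``."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    records = list(records)
    if not stratified:
        idx = rng.permutation(len(records))
        n_train = int(round(train_fraction * len(records)))
        train = [records[i] for i in idx[:n_train]]
        test = [records[i] for i in idx[n_train:]]
        return train, test
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        label = rec.label if hasattr(rec, "label") else rec[1]
        by_class.setdefault(label, []).append(i)
    train_idx, test_idx = [], []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members; cannot stratify")
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train = [records[i] for i in sorted(train_idx)]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


# ---------------------------------------------------------------------------
# disk I/O (8-bit grayscale PNG + manifest CSV)
# ---------------------------------------------------------------------------

def write_image_dir(images, manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write uint8 images as PNG plus ``manifest.csv`` (0-based row/col centers)."""
    from PIL import Image
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img, path in zip(images, manifest["path"]):
        Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(out / path)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_image_dir(path: str | Path):
    """Read back an image directory; returns ``(images, manifest_or_None)``."""
    from PIL import Image
    p = Path(path)
    manifest = None
    if (p / "manifest.csv").exists():
        manifest = pd.read_csv(p / "manifest.csv")
        files = [p / f for f in manifest["path"]]
    else:
        files = sorted(p.glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG images found under {p}")
    images = np.stack([np.asarray(Image.open(f).convert("L")) for f in files])
    return images, manifest
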