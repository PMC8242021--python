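"""Seeded synthetic imaging fixtures: classification and segmentation.

Two desk-scale dataset families emulate the *statistical shape* of the
package's two reference tasks without any external data:

* classification — grayscale "chest-film" style images.  Negatives are
  smoothed-noise backgrounds; positives additionally carry 1-3 soft
  elliptical bright "opacities".  The default class counts (1339 negative
  / 3824 positive) and the 85/15 train/validation split mirror the
  paediatric-pneumonia set-up, including its class imbalance.
* segmentation — image/mask pairs where each image contains one smooth
  random "organ" blob over a textured background and the mask is exactly
  the blob's support (binary, 0 background / 255 foreground).

Everything is drawn from a single seeded generator: the same seed yields
byte-identical PNGs and manifests.  The images are deliberately simple —
high-contrast structures with stationary noise — so tests that pass here
demonstrate mechanism correctness, not radiological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .data import DatasetManifest, split_counts

__all__ = [
    "GeneratorSpec",
    "generate_classification",
    "generate_segmentation",
    "augment",
    "load_split_arrays",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    Defaults reproduce the reference study conditions (class counts,
    image sizes, split fractions); ``n_images`` for segmentation is a
    scaled-down fixture default since the accounting of the full-size
    schedule needs no pixel data.
    """

    task: str = "classification"
    image_size: int = 224  # classification default; segmentation uses 256
    class_counts: tuple[int, int] = (1339, 3824)  # (negative, positive)
    n_images: int = 512  # segmentation only
    train_fraction: float = 0.85
    noise_level: float = 0.25  # background noise std on [0,1] scale
    opacity_intensity: tuple[float, float] = (0.30, 0.55)
    blob_radius_frac: tuple[float, float] = (0.18, 0.38)
    subjects_per: int = 4  # segmentation: consecutive images per subject
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.image_size < 32:
            raise ValueError("image size must be >= 32")
        if any(c < 1 for c in self.class_counts) or self.n_images < 1:
            raise ValueError("counts must be >= 1")


def _background(rng: np.random.Generator, size: int, noise_level: float
                ) -> np.ndarray:
    """Smoothed Gaussian noise on [0, 1], mid-grey mean."""
    raw = rng.normal(0.0, 1.0, (size, size))
    smooth = ndimage.gaussian_filter(raw, sigma=size / 32)
    smooth = smooth / (smooth.std() + 1e-9) * noise_level * 0.5
    return np.clip(0.45 + smooth, 0.0, 1.0)


def _elliptical_bump(size: int, cy: float, cx: float, ry: float, rx: float,
                     angle: float, amplitude: float) -> np.ndarray:
    """A soft (Gaussian-profile) ellipse; the 'opacity' primitive."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ca, sa = math.cos(angle), math.sin(angle)
    dy, dx = yy - cy, xx - cx
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    return amplitude * np.exp(-0.5 * (u**2 + v**2) * 4.0)


def _classification_image(rng: np.random.Generator, size: int,
                          positive: bool, spec: GeneratorSpec) -> np.ndarray:
    img = _background(rng, size, spec.noise_level)
    if positive:
        lo, hi = spec.opacity_intensity
        for _ in range(int(rng.integers(1, 4))):
            img += _elliptical_bump(
                size,
                cy=rng.uniform(0.25, 0.75) * size,
                cx=rng.uniform(0.25, 0.75) * size,
                ry=rng.uniform(0.10, 0.22) * size,
                rx=rng.uniform(0.10, 0.22) * size,
                angle=rng.uniform(0, math.pi),
                amplitude=rng.uniform(lo, hi),
            )
    return (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


def _blob_mask(rng: np.random.Generator, size: int,
               radius_frac: tuple[float, float]) -> np.ndarray:
    """Support of a smooth star-convex blob: r(theta) as a short Fourier
    series around a random centre."""
    base_r = rng.uniform(*radius_frac) * size
    cy = rng.uniform(0.35, 0.65) * size
    cx = rng.uniform(0.35, 0.65) * size
    n_harm = 4
    amps = rng.uniform(0.0, 0.18, n_harm) * base_r
    phases = rng.uniform(0, 2 * math.pi, n_harm)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(yy - cy, xx - cx)
    r_of_theta = base_r + sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases))
    )
    return rr <= r_of_theta


def _segmentation_pair(rng: np.random.Generator, size: int,
                       spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    img = _background(rng, size, spec.noise_level)
    mask = _blob_mask(rng, size, spec.blob_radius_frac)
    contrast = rng.uniform(0.30, 0.45)
    img = img + contrast * mask
    img = np.clip(img + rng.normal(0, 0.03, img.shape), 0.0, 1.0)
    return (img * 255).astype(np.uint8), np.where(mask, 255, 0).astype(np.uint8)


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(arr, mode="L").save(path)


def generate_classification(spec: GeneratorSpec, out_dir: str | Path
                            ) -> DatasetManifest:
    """Write the classification fixture and its manifest CSV.

    Negative images are pure backgrounds (label 0); positives carry
    opacities (label 1).  Records are shuffled, then split 85/15 into
    train/validation by the half-up rule.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_neg, n_pos = spec.class_counts
    labels = np.array([0] * n_neg + [1] * n_pos)
    order = rng.permutation(labels.size)
    labels = labels[order]

    rows = []
    for i, label in enumerate(labels):
        img = _classification_image(rng, spec.image_size, bool(label), spec)
        p = out / f"img_{i:05d}.png"
        _save_png(img, p)
        rows.append({"path": str(p), "label": int(label), "split": "train"})

    n = len(rows)
    n_train, _ = split_counts(n, spec.train_fraction)
    assign = rng.permutation(n)
    for j in assign[n_train:]:
        rows[j]["split"] = "val"
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.to_csv(out / "manifest.csv")
    return manifest


def generate_segmentation(spec: GeneratorSpec, out_dir: str | Path
                          ) -> DatasetManifest:
    """Write the segmentation fixture: image/mask PNG pairs plus manifest.

    Consecutive images share a subject id (emulating slices of one
    patient) and splits are assigned per whole subject — strict subject
    independence between train/val/test.  Split fractions follow the
    reference study's 5184/640/2560 proportions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    n = spec.n_images

    rows = []
    for i in range(n):
        img, mask = _segmentation_pair(rng, size, spec)
        ip, mp = out / f"img_{i:05d}.png", out / f"mask_{i:05d}.png"
        _save_png(img, ip)
        _save_png(mask, mp)
        rows.append({
            "path": str(ip), "label": 1, "mask_path": str(mp),
            "subject_id": f"subj_{i // spec.subjects_per:04d}", "split": "train",
        })

    # subject-disjoint split at ~5184:640:2560 proportions
    fractions = np.array([5184.0, 640.0, 2560.0])
    fractions /= fractions.sum()
    subjects = sorted({r["subject_id"] for r in rows})
    subjects = list(np.array(subjects)[rng.permutation(len(subjects))])
    n_train_subj = max(1, round(fractions[0] * len(subjects)))
    n_val_subj = max(1, round(fractions[1] * len(subjects)))
    split_of = {}
    for k, s in enumerate(subjects):
        if k < n_train_subj:
            split_of[s] = "train"
        elif k < n_train_subj + n_val_subj:
            split_of[s] = "val"
        else:
            split_of[s] = "test"
    for r in rows:
        r["split"] = split_of[r["subject_id"]]
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.to_csv(out / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_CLS_FAMILIES = ("rotate", "scale", "translate", "shear")
_SEG_FAMILIES = ("rotate", "translate", "scale", "flip")


def _affine_matrix(angle_deg: float, scale: float, shear_deg: float,
                   ty: float, tx: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Output->input matrix and offset about the image centre."""
    a = math.radians(angle_deg)
    sh = math.radians(shear_deg)
    fwd = np.array([
        [scale * math.cos(a), -scale * math.sin(a) + math.tan(sh)],
        [scale * math.sin(a), scale * math.cos(a)],
    ])
    inv = np.linalg.inv(fwd)
    c = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    offset = c - inv @ (c + np.array([ty, tx]))
    return inv, offset


def augment(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    kind: str = "classification",
    seed: int | None = None,
    params: dict | None = None,
):
    """Random augmentation matching each task's transform families.

    classification: affine (rotation, scaling, translation, shearing) on
    the image only; passing a mask is a misuse error.
    segmentation: affine (rotation, translation, scaling, flipping) plus
    additive Gaussian noise on the *image only*; the identical geometric
    transform is applied to image and mask, with bilinear resampling for
    the image and nearest-neighbour for the mask so masks stay binary.

    ``params`` overrides the random draw (keys: angle, scale, shear, ty,
    tx, flip, noise_std); identity parameters return the inputs unchanged.
    Right-angle rotations without any other transform are performed
    exactly on the discrete grid (so e.g. a 90-degree rotation preserves
    mask foreground counts exactly).
    """
    if kind not in ("classification", "segmentation"):
        raise ValueError(f"unknown augmentation kind {kind!r}")
    if kind == "classification" and mask is not None:
        raise ValueError("masks are a segmentation concept; "
                         "classification augmentation takes the image only")
    rng = np.random.default_rng(seed)
    size = image.shape[0]
    if params is None:
        params = {
            "angle": rng.uniform(-15, 15),
            "scale": rng.uniform(0.9, 1.1),
            "ty": rng.uniform(-0.1, 0.1) * size,
            "tx": rng.uniform(-0.1, 0.1) * size,
        }
        if kind == "classification":
            params["shear"] = rng.uniform(-10, 10)
        else:
            params["flip"] = bool(rng.integers(0, 2))
            params["noise_std"] = 0.02 * 255
    angle = params.get("angle", 0.0)
    scale = params.get("scale", 1.0)
    shear = params.get("shear", 0.0)
    ty, tx = params.get("ty", 0.0), params.get("tx", 0.0)
    flip = params.get("flip", False)
    noise_std = params.get("noise_std", 0.0)

    img = image.astype(np.float64)
    affine_free = scale == 1.0 and shear == 0.0 and ty == 0.0 and tx == 0.0
    if affine_free and angle % 90 == 0:
        k = int(angle // 90) % 4
        img = np.rot90(img, k)
        out_mask = None if mask is None else np.rot90(mask, k)
    else:
        inv, offset = _affine_matrix(angle, scale, shear, ty, tx, size)
        img = ndimage.affine_transform(img, inv, offset=offset, order=1,
                                       mode="nearest")
        out_mask = None
        if mask is not None:
            out_mask = ndimage.affine_transform(mask, inv, offset=offset,
                                                order=0, mode="nearest")
    if flip:
        img = img[:, ::-1]
        if out_mask is not None:
            out_mask = out_mask[:, ::-1]
    if noise_std:
        img = img + rng.normal(0.0, noise_std, img.shape)
    img = np.clip(img, 0, 255).astype(image.dtype)
    if mask is None:
        return img
    return img, np.ascontiguousarray(out_mask)


def load_split_arrays(manifest: DatasetManifest, split: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Load one split as float arrays scaled to [0, 1].

    Returns ``(images, labels)`` for classification manifests and
    ``(images, masks)`` when a mask column is present; images gain a
    leading channel axis (B, 1, H, W).
    """
    sub = manifest.subset(split).records
    imgs = np.stack([
        np.asarray(Image.open(p), dtype=np.float64) / 255.0 for p in sub["path"]
    ])[:, None, :, :]
    if "mask_path" in sub.columns and sub["mask_path"].notna().all():
        masks = np.stack([
            (np.asarray(Image.open(p), dtype=np.float64) > 127).astype(np.float64)
            for p in sub["mask_path"]
        ])[:, None, :, :]
        return imgs, masks
    return imgs, sub["label"].to_numpy()
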