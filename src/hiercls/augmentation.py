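"""Training-set augmentation and class-balancing oversampling.

Four operators — additive intensity shift, rotation, flips, and integer
translation — are composed (optionally at random) to produce augmented
copies of training images.  An oversampling plan assigns each minority-class
source image an integer number of extra augmented copies so that, within
each magnification, every subclass reaches the count of the largest class
exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from hiercls.data_io import ImageRecord, Manifest

__all__ = [
    "AugmentationSpec",
    "OversamplingPlan",
    "apply_augmentation",
    "build_oversampling_plan",
    "materialize_augmented_set",
    "load_image",
    "save_image",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Operator parameters; defaults follow the standard recipe: intensity
    shift in [-0.1, 0.1] on [0,1]-normalized channels, rotation in
    [-90, 90] degrees, horizontal+vertical flips, translation up to
    20 px, randomly combined."""

    intensity_range: tuple[float, float] = (-0.1, 0.1)
    rotation_range_deg: tuple[float, float] = (-90.0, 90.0)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    translation_px: int = 20
    combine: bool = True
    multiplicative_intensity: bool = False

    def __post_init__(self) -> None:
        if self.intensity_range[0] > self.intensity_range[1]:
            raise ValueError("intensity_range must be ordered")
        if self.rotation_range_deg[0] > self.rotation_range_deg[1]:
            raise ValueError("rotation_range_deg must be ordered")
        if self.translation_px < 0:
            raise ValueError("translation_px must be >= 0")


def load_image(path) -> np.ndarray:
    """Read an RGB image as a float array in [0, 1], shape (H, W, 3)."""
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    return arr


def save_image(arr: np.ndarray, path) -> None:
    """Write a [0, 1] float RGB array as 8-bit PNG."""
    out = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(out).save(path)


def apply_augmentation(image: np.ndarray, spec: AugmentationSpec, rng_seed: int) -> np.ndarray:
    """Apply the (optionally random) composition of the four operators.

    Fixed composition order: intensity -> rotation -> flip -> translation.
    Rotation and translation use reflect padding; intensity output is
    clipped to [0, 1].  Deterministic for a given seed; operators whose
    sampled parameter is exactly zero are skipped, so an all-zero spec is
    the identity.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected 3-channel RGB image, got shape {img.shape}")
    rng = np.random.default_rng(rng_seed)
    if spec.combine:
        use = rng.random(4) < 0.5
    else:
        use = np.ones(4, dtype=bool)

    # intensity
    if use[0]:
        shift = rng.uniform(*spec.intensity_range)
        if shift != 0.0:
            img = img * (1.0 + shift) if spec.multiplicative_intensity else img + shift
            img = np.clip(img, 0.0, 1.0)
    # rotation (bilinear, reflect fill)
    if use[1]:
        angle = rng.uniform(*spec.rotation_range_deg)
        if angle != 0.0:
            img = _sk_rotate(img, angle, resize=False, mode="reflect", order=1, clip=True)
    # flips
    if use[2]:
        if spec.flip_horizontal and rng.random() < 0.5:
            img = img[:, ::-1]
        if spec.flip_vertical and rng.random() < 0.5:
            img = img[::-1]
    # translation (integer pixels, reflect fill)
    if use[3] and spec.translation_px > 0:
        dy, dx = rng.integers(-spec.translation_px, spec.translation_px + 1, size=2)
        if dy or dx:
            img = np.stack(
                [ndimage.shift(img[..., c], (dy, dx), order=0, mode="reflect") for c in range(3)],
                axis=-1,
            )
    return np.ascontiguousarray(img)


@dataclass(frozen=True)
class OversamplingPlan:
    """Extra augmented copies per source image, keyed by
    (subclass, magnification).

    For each key the value is ``(count, base, n_plus_one)``: every source
    image receives ``base`` extra copies and the first ``n_plus_one`` of
    them (in manifest order) one more, so totals reach the per-magnification
    maximum exactly.
    """

    entries: dict

    def copies_for(self, subclass: str, magnification: str) -> list[int]:
        count, base, n_plus = self.entries[(subclass, magnification)]
        return [base + 1 if i < n_plus else base for i in range(count)]

    def total_after(self, subclass: str, magnification: str) -> int:
        count, base, n_plus = self.entries[(subclass, magnification)]
        return count * (1 + base) + n_plus


def build_oversampling_plan(counts: dict) -> OversamplingPlan:
    """Balance class counts within each magnification to the max class.

    ``counts`` maps (subclass, magnification) -> image count (all >= 1).
    """
    by_mag: dict[str, dict[str, int]] = {}
    for (sub, mag), c in counts.items():
        if c < 1:
            raise ValueError(f"zero-count class: {(sub, mag)}")
        by_mag.setdefault(mag, {})[sub] = int(c)
    entries = {}
    for mag, sub_counts in by_mag.items():
        target = max(sub_counts.values())
        for sub, c in sub_counts.items():
            extra = target - c
            entries[(sub, mag)] = (c, extra // c, extra % c)
    return OversamplingPlan(entries)


def materialize_augmented_set(
    m: Manifest,
    plan: OversamplingPlan,
    spec: AugmentationSpec,
    out_dir,
    rng_seed: int = 0,
) -> Manifest:
    """Write augmented copies of training images and return the extended
    manifest.

    Augmented records inherit the source's patient ID and subclass, carry an
    ``augmented_from`` column, and are always in the train split.  A plan
    that references counts not matching the train split (i.e. built from
    val/test records) is rejected — the leakage guard.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train = [r for r in m.records if r.split == "train"]
    if not train:
        raise ValueError("manifest has no train split; augment after splitting")
    train_counts = {}
    for r in train:
        key = (m.taxonomy.canonical(r.subclass), r.magnification)
        train_counts[key] = train_counts.get(key, 0) + 1
    for key, (count, _, _) in plan.entries.items():
        if train_counts.get(key) != count:
            raise ValueError(
                f"oversampling plan for {key} built from {count} images but train split "
                f"has {train_counts.get(key, 0)}; plan must be built from the train split only"
            )

    root = Path(m.root)
    new_records = list(m.records)
    for key in sorted(plan.entries):
        sub, mag = key
        sources = [
            r for r in train if m.taxonomy.canonical(r.subclass) == sub and r.magnification == mag
        ]
        copies = plan.copies_for(sub, mag)
        for i, (rec, n_copies) in enumerate(zip(sources, copies)):
            if n_copies == 0:
                continue
            img = load_image(root / rec.path)
            for c in range(n_copies):
                # stable seed: Python's hash() is salted per process
                tag = zlib.crc32(f"{sub}|{mag}|{i}|{c}".encode())
                seed = np.random.SeedSequence([rng_seed, tag]).generate_state(1)[0]
                aug = apply_augmentation(img, spec, rng_seed=int(seed))
                stem = Path(rec.path).stem
                rel = f"aug/{sub}_{mag}_{stem}_c{c}.png"
                (out_dir / "aug").mkdir(exist_ok=True)
                save_image(aug, out_dir / rel)
                new_records.append(
                    ImageRecord(
                        path=str((out_dir / rel).relative_to(root))
                        if out_dir.is_relative_to(root)
                        else str(out_dir / rel),
                        patient_id=rec.patient_id,
                        subclass=rec.subclass,
                        magnification=rec.magnification,
                        split="train",
                        augmented_from=rec.path,
                    )
                )
    return replace(m, records=tuple(new_records))
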