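"""Synthetic hierarchical histology-shaped dataset generator.

Produces a manifest plus RGB images whose statistics carry a two-level
class structure: a superclass-level color field, a subclass-level band-pass
texture (distinct orientation and color tint per subclass, weaker than the
superclass signal), a per-patient random offset shared by all of a
patient's images, and Gaussian pixel noise.  Magnification is simulated by
rescaling the texture frequency.  The built-in hierarchy — same-subclass
pairs closer than same-superclass pairs, which are closer than
cross-superclass pairs — is exactly the structure the distance-constraint
loss is designed to enforce, making this a ground-truth testbed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hiercls.augmentation import save_image
from hiercls.data_io import ImageRecord, Manifest, write_manifest
from hiercls.hierarchy import Taxonomy, default_breakhis_taxonomy

__all__ = ["SyntheticConfig", "generate_dataset", "render_image", "expected_separability"]

#: texture frequency multiplier per simulated magnification
_MAG_SCALE = {"40X": 1.0, "100X": 1.6, "200X": 2.4, "400X": 3.4}

# fixed unit color tints, one per within-superclass subclass slot
_SUBCLASS_TINTS = np.array(
    [
        [1.0, -0.5, -0.5],
        [-0.5, 1.0, -0.5],
        [-0.5, -0.5, 1.0],
        [1.0, -1.0, 0.0],
    ]
)
_SUBCLASS_TINTS /= np.linalg.norm(_SUBCLASS_TINTS, axis=1, keepdims=True)

# opposite superclass color directions
_SUPER_DIRS = np.array([[1.0, -0.6, -0.4], [-1.0, 0.6, 0.4]])
_SUPER_DIRS /= np.linalg.norm(_SUPER_DIRS, axis=1, keepdims=True)


@dataclass(frozen=True)
class SyntheticConfig:
    taxonomy: Taxonomy = field(default_factory=default_breakhis_taxonomy)
    patients_per_subclass: int = 4
    images_per_patient: int = 8
    image_size: int = 64
    magnifications: tuple[str, ...] = ("40X",)
    superclass_effect: float = 0.25
    subclass_effect: float = 0.12
    patient_effect: float = 0.03
    noise_sd: float = 0.04
    imbalance_ratios: dict | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.superclass_effect, self.subclass_effect, self.patient_effect) < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.subclass_effect >= self.superclass_effect and self.superclass_effect > 0:
            raise ValueError("subclass_effect must be < superclass_effect")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        for m in self.magnifications:
            if m not in _MAG_SCALE:
                raise ValueError(f"unknown magnification {m!r}")

    def images_for(self, subclass: str) -> int:
        ratio = 1.0 if not self.imbalance_ratios else self.imbalance_ratios.get(subclass, 1.0)
        return int(round(self.images_per_patient * ratio))


def _seed_for(cfg_seed: int, *parts) -> int:
    tag = zlib.crc32("|".join(str(p) for p in parts).encode())
    return int(np.random.SeedSequence([cfg_seed, tag]).generate_state(1)[0])


def _patient_offset(cfg: SyntheticConfig, subclass: str, p_idx: int) -> np.ndarray:
    rng = np.random.default_rng(_seed_for(cfg.rng_seed, "patient", subclass, p_idx))
    v = rng.normal(size=3)
    return cfg.patient_effect * v / np.linalg.norm(v)


def render_image(
    cfg: SyntheticConfig,
    subclass: str,
    patient_offset: np.ndarray,
    magnification: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one synthetic image as a [0,1] float array (H, W, 3)."""
    t = cfg.taxonomy
    sub = t.canonical(subclass)
    sup_idx = t.superclasses.index(t.subclass_map[sub])
    siblings = [s for s, p in t.subclass_map.items() if p == t.subclass_map[sub]]
    slot = siblings.index(sub) % 4

    s = cfg.image_size
    yy, xx = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")

    base = 0.55 + cfg.superclass_effect * _SUPER_DIRS[sup_idx % 2]
    img = np.ones((s, s, 3)) * base

    # subclass tint (weak color component)
    img += 0.6 * cfg.subclass_effect * _SUBCLASS_TINTS[slot]

    # subclass band-pass texture: orientation encodes the within-superclass
    # slot, frequency shifts with superclass and simulated magnification
    theta = slot * np.pi / 4
    freq = (3.0 + 2.0 * sup_idx) * _MAG_SCALE[magnification]
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) / s + phase)
    img += (cfg.subclass_effect * 0.8 + 0.02) * wave[..., None]

    img += patient_offset[None, None, :]
    img += rng.normal(scale=cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(cfg: SyntheticConfig, out_dir) -> Manifest:
    """Write the synthetic dataset (PNG tree + manifest CSV) and return the
    manifest.  Fully deterministic for a given ``cfg.rng_seed``."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    t = cfg.taxonomy
    records = []
    for sub in t.subclasses:
        sup = t.subclass_map[sub]
        n_img = cfg.images_for(sub)
        for p in range(cfg.patients_per_subclass):
            patient_id = f"{sub}_p{p:02d}"
            offset = _patient_offset(cfg, sub, p)
            for mag in cfg.magnifications:
                for i in range(n_img):
                    rng = np.random.default_rng(
                        _seed_for(cfg.rng_seed, "image", sub, p, mag, i)
                    )
                    img = render_image(cfg, sub, offset, mag, rng)
                    rel = Path(sup) / sub / patient_id / mag / f"img{i:03d}.png"
                    (out_dir / rel).parent.mkdir(parents=True, exist_ok=True)
                    save_image(img, out_dir / rel)
                    records.append(
                        ImageRecord(
                            path=str(rel),
                            patient_id=patient_id,
                            subclass=sub,
                            magnification=mag,
                        )
                    )
    manifest = Manifest(tuple(records), t, root=str(out_dir))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def _image_feature(img: np.ndarray) -> np.ndarray:
    """Simple statistics used by the separability probe: channel means plus
    a coarse orientation-energy signature of the luminance spectrum."""
    means = img.mean(axis=(0, 1))
    lum = img.mean(axis=2)
    f = np.abs(np.fft.fftshift(np.fft.fft2(lum - lum.mean())))
    s = f.shape[0]
    cy = cx = s // 2
    yy, xx = np.meshgrid(np.arange(s) - cy, np.arange(s) - cx, indexing="ij")
    ang = np.arctan2(yy, xx) % np.pi
    r = np.hypot(yy, xx)
    band = (r > 1) & (r < s / 2)
    bins = np.minimum((ang / (np.pi / 4)).astype(int), 3)
    energy = np.array([f[band & (bins == b)].sum() for b in range(4)])
    energy = energy / max(energy.sum(), 1e-12)
    return np.concatenate([means, 0.1 * energy])


def expected_separability(
    cfg: SyntheticConfig, n_pairs: int = 500, rng_seed: int = 0
) -> dict:
    """Monte-Carlo estimate of the three-tier distance structure.

    Samples image pairs, computes simple statistics, and reports mean
    feature distances for same-subclass, same-superclass and
    cross-superclass pairs, whether the tier ordering holds, and whether
    the patient effect dominates the subclass effect (in which case
    image-wise splits leak identity and patient-wise splitting is
    required for honest evaluation).
    """
    rng = np.random.default_rng(rng_seed)
    t = cfg.taxonomy
    subs = t.subclasses
    mag = cfg.magnifications[0]
    tiers = {"same_subclass": [], "same_superclass": [], "different_superclass": []}

    def _sample(sub):
        p = int(rng.integers(cfg.patients_per_subclass))
        img = render_image(cfg, sub, _patient_offset(cfg, sub, p), mag, rng)
        return _image_feature(img)

    for _ in range(n_pairs):
        tier = rng.choice(list(tiers))
        a = subs[int(rng.integers(len(subs)))]
        if tier == "same_subclass":
            b = a
        elif tier == "same_superclass":
            sibs = t.siblings(a)
            b = sibs[int(rng.integers(len(sibs)))]
        else:
            others = [s for s in subs if t.subclass_map[s] != t.subclass_map[a]]
            b = others[int(rng.integers(len(others)))]
        tiers[tier].append(float(np.linalg.norm(_sample(a) - _sample(b))))

    means = {k: float(np.mean(v)) for k, v in tiers.items()}
    ordered = (
        means["same_subclass"] < means["same_superclass"] < means["different_superclass"]
    )
    non_separable = cfg.superclass_effect == 0 and cfg.subclass_effect == 0
    return {
        "mean_distance": means,
        "hierarchy_ordered": bool(ordered and not non_separable),
        "non_separable": non_separable,
        "patient_split_required": cfg.patient_effect > cfg.subclass_effect,
    }
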