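"""Image manifests, patient-wise splitting, and cross-validation folds.

A manifest is one row per image: relative file path, patient ID, subclass,
magnification, and an optional split assignment.  Splits are always made by
patient — no subject ever contributes images to more than one of
train/validation/test — and stratified by subclass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hiercls.hierarchy import Taxonomy, default_breakhis_taxonomy

__all__ = [
    "MAGNIFICATIONS",
    "ImageRecord",
    "Manifest",
    "read_manifest",
    "write_manifest",
    "scan_breakhis_tree",
    "patient_wise_split",
    "make_cv_folds",
    "audit_no_leakage",
]

MAGNIFICATIONS = ("40X", "100X", "200X", "400X")
SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ["path", "patient_id", "subclass", "magnification", "split"]


@dataclass(frozen=True)
class ImageRecord:
    """One labelled image: path (relative to the manifest root), patient,
    subclass, magnification, optional split, optional augmentation source."""

    path: str
    patient_id: str
    subclass: str
    magnification: str
    split: str | None = None
    augmented_from: str | None = None


@dataclass(frozen=True)
class Manifest:
    records: tuple[ImageRecord, ...]
    taxonomy: Taxonomy
    root: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        errors = []
        paths = set()
        patient_sub: dict[str, str] = {}
        for i, r in enumerate(self.records):
            if r.path in paths:
                errors.append(f"row {i}: duplicate path {r.path!r}")
            paths.add(r.path)
            try:
                canon = self.taxonomy.canonical(r.subclass)
            except KeyError:
                errors.append(f"row {i}: invalid subclass {r.subclass!r}")
                continue
            if r.magnification not in MAGNIFICATIONS:
                errors.append(f"row {i}: invalid magnification {r.magnification!r}")
            if r.split is not None and r.split not in SPLITS:
                errors.append(f"row {i}: invalid split {r.split!r}")
            prev = patient_sub.setdefault(r.patient_id, canon)
            if prev != canon:
                errors.append(
                    f"row {i}: patient {r.patient_id!r} has inconsistent subclasses "
                    f"({prev!r} vs {canon!r})"
                )
        if errors:
            raise ValueError("invalid manifest:\n  " + "\n  ".join(errors))

    def __len__(self) -> int:
        return len(self.records)

    def patients(self) -> list[str]:
        return list(dict.fromkeys(r.patient_id for r in self.records))

    def patient_subclass(self) -> dict[str, str]:
        return {r.patient_id: self.taxonomy.canonical(r.subclass) for r in self.records}

    def subset(self, split: str) -> "Manifest":
        recs = tuple(r for r in self.records if r.split == split)
        if not recs:
            raise ValueError(f"split {split!r} is empty")
        return replace(self, records=recs)

    def counts(self, by_magnification: bool = True) -> dict:
        """Image counts per (subclass, magnification) or per subclass."""
        out: dict = {}
        for r in self.records:
            key = (
                (self.taxonomy.canonical(r.subclass), r.magnification)
                if by_magnification
                else self.taxonomy.canonical(r.subclass)
            )
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [r.path for r in self.records],
                "patient_id": [r.patient_id for r in self.records],
                "subclass": [r.subclass for r in self.records],
                "magnification": [r.magnification for r in self.records],
                "split": [r.split or "" for r in self.records],
                "augmented_from": [r.augmented_from or "" for r in self.records],
            }
        )


def write_manifest(m: Manifest, path) -> None:
    m.to_frame().to_csv(path, index=False)


def read_manifest(path, taxonomy: Taxonomy | None = None, root: str | None = None) -> Manifest:
    """Read a manifest CSV (``path,patient_id,subclass,magnification,split``).

    Missing required columns and invalid labels raise labelled errors with
    row numbers.
    """
    taxonomy = taxonomy or default_breakhis_taxonomy()
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples()):
        records.append(
            ImageRecord(
                path=row.path,
                patient_id=row.patient_id,
                subclass=row.subclass,
                magnification=row.magnification,
                split=(getattr(row, "split", "") or None),
                augmented_from=(getattr(row, "augmented_from", "") or None),
            )
        )
    return Manifest(tuple(records), taxonomy, root=root or str(Path(path).parent))


def scan_breakhis_tree(root, taxonomy: Taxonomy | None = None) -> Manifest:
    """Build a manifest by walking a BreaKHis-style directory layout:
    ``<root>/<superclass>/<tumor_type>/<patient_id>/<magnification>/<image>``.
    """
    taxonomy = taxonomy or default_breakhis_taxonomy()
    root = Path(root)
    records = []
    for img in sorted(root.rglob("*")):
        if img.suffix.lower() not in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}:
            continue
        mag = img.parent.name
        patient = img.parent.parent.name
        tumor = img.parent.parent.parent.name
        records.append(
            ImageRecord(
                path=str(img.relative_to(root)),
                patient_id=patient,
                subclass=taxonomy.canonical(tumor),
                magnification=mag,
            )
        )
    if not records:
        raise ValueError(f"no images found under {root}")
    return Manifest(tuple(records), taxonomy, root=str(root))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _global_targets(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Round-to-nearest train and val counts; test receives the remainder."""
    f_tr, f_val, f_te = fractions
    n_tr = int(round(n * f_tr))
    n_val = int(round(n * f_val))
    n_te = n - n_tr - n_val
    if min(n_tr, n_val, n_te) < 0:
        raise ValueError(f"fractions {fractions} infeasible for {n} patients")
    return n_tr, n_val, n_te


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `weights`."""
    if total == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def patient_wise_split(
    m: Manifest,
    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25),
    rng_seed: int = 0,
) -> Manifest:
    """Assign train/val/test splits by patient, stratified by subclass.

    Global split sizes follow a round-to-nearest rule with the test split
    receiving the remainder; per-subclass allocations are apportioned by
    largest remainder so stratification stays within one patient of the
    target proportions.  A subclass with a single patient cannot be
    stratified and is assigned to train with a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) <= 0:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    rng = np.random.default_rng(rng_seed)
    pat_sub = m.patient_subclass()
    by_sub: dict[str, list[str]] = {}
    for pat, sub in pat_sub.items():
        by_sub.setdefault(sub, []).append(pat)

    singletons = {c for c, pats in by_sub.items() if len(pats) == 1}
    for c in singletons:
        warnings.warn(f"subclass {c!r} has a single patient; assigned to train", stacklevel=2)
    multi = {c: pats for c, pats in by_sub.items() if c not in singletons}
    if any(len(pats) < 3 for pats in multi.values()):
        warnings.warn("some subclasses have < 3 patients; stratification is coarse", stacklevel=2)

    n_strat = sum(len(p) for p in multi.values())
    n_tr, n_val, n_te = _global_targets(n_strat, fractions)
    subs = sorted(multi)
    weights = np.array([len(multi[c]) for c in subs], dtype=float)
    alloc_val = _largest_remainder(weights, n_val)
    alloc_te = _largest_remainder(weights, n_te)
    # cap per-subclass val+test so every subclass keeps >= 1 train patient
    assignment: dict[str, str] = {p: "train" for c in singletons for p in by_sub[c]}
    for c, a_val, a_te in zip(subs, alloc_val, alloc_te):
        pats = sorted(multi[c])
        order = rng.permutation(len(pats))
        a_val = min(a_val, max(0, len(pats) - a_te - 1))
        for j, pi in enumerate(order):
            if j < a_te:
                assignment[pats[pi]] = "test"
            elif j < a_te + a_val:
                assignment[pats[pi]] = "val"
            else:
                assignment[pats[pi]] = "train"
    new_records = tuple(replace(r, split=assignment[r.patient_id]) for r in m.records)
    return replace(m, records=new_records)


def make_cv_folds(m: Manifest, n_folds: int = 5, rng_seed: int = 0) -> list[Manifest]:
    """Stratified patient-wise cross-validation folds.

    Patients are partitioned into ``n_folds`` groups stratified by subclass;
    fold ``i`` uses group ``i`` as test, group ``i+1`` as validation and the
    rest as training, so every patient appears in exactly one test set.
    """
    patients = m.patients()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(patients):
        raise ValueError(f"n_folds={n_folds} exceeds patient count {len(patients)}")
    rng = np.random.default_rng(rng_seed)
    pat_sub = m.patient_subclass()
    by_sub: dict[str, list[str]] = {}
    for pat in patients:
        by_sub.setdefault(pat_sub[pat], []).append(pat)
    group: dict[str, int] = {}
    offset = 0
    for sub in sorted(by_sub):
        pats = sorted(by_sub[sub])
        order = rng.permutation(len(pats))
        for j, pi in enumerate(order):
            group[pats[pi]] = (j + offset) % n_folds
        offset += len(pats)  # rotate start so small classes spread over folds
    folds = []
    for i in range(n_folds):
        val_g = (i + 1) % n_folds
        assignment = {
            p: ("test" if g == i else "val" if g == val_g else "train")
            for p, g in group.items()
        }
        folds.append(
            replace(m, records=tuple(replace(r, split=assignment[r.patient_id]) for r in m.records))
        )
    return folds


def audit_no_leakage(augmented: Manifest, base: Manifest) -> None:
    """Fail loudly if any augmented image derives from a val/test patient.

    Augmentation must only touch the training split; this cross-checks every
    augmented record's patient against the base manifest's split assignment.
    """
    holdout = {r.patient_id for r in base.records if r.split in ("val", "test")}
    leaks = [
        r.path
        for r in augmented.records
        if r.augmented_from is not None and r.patient_id in holdout
    ]
    if leaks:
        raise ValueError(
            f"leakage: {len(leaks)} augmented images from val/test patients, e.g. {leaks[:3]}"
        )
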