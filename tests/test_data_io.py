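import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hiercls.data_io import (
    ImageRecord,
    Manifest,
    audit_no_leakage,
    make_cv_folds,
    patient_wise_split,
    read_manifest,
    scan_breakhis_tree,
    write_manifest,
)


def toy_manifest(taxonomy, n_patients_per_sub=4, images_per_patient=3, subs=None):
    subs = subs or taxonomy.subclasses
    records = []
    for sub in subs:
        for p in range(n_patients_per_sub):
            pid = f"{sub}-{p}"
            for i in range(images_per_patient):
                records.append(
                    ImageRecord(f"{sub}/{pid}/img{i}.png", pid, sub, "40X")
                )
    return Manifest(tuple(records), taxonomy)


class TestManifestValidation:
    def test_round_trip(self, taxonomy, tmp_path):
        m = toy_manifest(taxonomy)
        write_manifest(m, tmp_path / "m.csv")
        again = read_manifest(tmp_path / "m.csv", taxonomy)
        assert set(r.path for r in again.records) == set(r.path for r in m.records)
        assert len(again) == len(m)

    def test_invalid_magnification_names_row(self, taxonomy, tmp_path):
        df = pd.DataFrame(
            {
                "path": ["a.png", "b.png"],
                "patient_id": ["p1", "p2"],
                "subclass": ["A", "F"],
                "magnification": ["40X", "4000X"],
            }
        )
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="row 1.*4000X"):
            read_manifest(tmp_path / "bad.csv", taxonomy)

    def test_missing_column(self, taxonomy, tmp_path):
        pd.DataFrame({"path": ["a.png"]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            read_manifest(tmp_path / "bad.csv", taxonomy)

    def test_duplicate_paths_rejected(self, taxonomy):
        r = ImageRecord("x.png", "p1", "A", "40X")
        with pytest.raises(ValueError, match="duplicate path"):
            Manifest((r, r), taxonomy)

    def test_inconsistent_patient_subclass_rejected(self, taxonomy):
        with pytest.raises(ValueError, match="inconsistent"):
            Manifest(
                (
                    ImageRecord("a.png", "p1", "A", "40X"),
                    ImageRecord("b.png", "p1", "F", "40X"),
                ),
                taxonomy,
            )

    def test_directory_scan_counts(self, taxonomy, tmp_path):
        layout = {
            ("benign", "adenosis", "pA1", "40X"): 3,
            ("benign", "fibroadenoma", "pF1", "100X"): 2,
            ("malignant", "ductal_carcinoma", "pD1", "40X"): 4,
        }
        for (sup, sub, pid, mag), n in layout.items():
            d = tmp_path / sup / sub / pid / mag
            d.mkdir(parents=True)
            for i in range(n):
                (d / f"im{i}.png").write_bytes(b"\x89PNG fake")
        m = scan_breakhis_tree(tmp_path, taxonomy)
        assert len(m) == 9
        counts = m.counts()
        assert counts[("A", "40X")] == 3
        assert counts[("F", "100X")] == 2
        assert counts[("DC", "40X")] == 4


class TestPatientWiseSplit:
    def test_82_patients_yield_21_test(self, taxonomy):
        # 82 patients spread over the 8 subclasses like the benchmark's scale
        per_sub = [11, 10, 10, 10, 11, 10, 10, 10]
        records = []
        for sub, n in zip(taxonomy.subclasses, per_sub):
            for p in range(n):
                records.append(ImageRecord(f"{sub}{p}.png", f"{sub}-{p}", sub, "40X"))
        m = Manifest(tuple(records), taxonomy)
        split = patient_wise_split(m, (0.50, 0.25, 0.25), rng_seed=0)
        by_split = {}
        for r in split.records:
            by_split.setdefault(r.split, set()).add(r.patient_id)
        assert len(by_split["test"]) == 21
        assert len(by_split["train"]) + len(by_split["val"]) == 61

    def test_no_patient_in_two_splits(self, taxonomy):
        m = toy_manifest(taxonomy)
        for seed in range(10):
            split = patient_wise_split(m, rng_seed=seed)
            seen = {}
            for r in split.records:
                assert seen.setdefault(r.patient_id, r.split) == r.split

    def test_stratification_within_one_patient(self, taxonomy):
        m = toy_manifest(taxonomy, n_patients_per_sub=5)
        split = patient_wise_split(m, (0.5, 0.25, 0.25), rng_seed=1)
        pat_split = {r.patient_id: r.split for r in split.records}
        pat_sub = {r.patient_id: r.subclass for r in split.records}
        for sub in taxonomy.subclasses:
            pats = [p for p in pat_split if pat_sub[p] == sub]
            n_test = sum(pat_split[p] == "test" for p in pats)
            assert abs(n_test - 0.25 * len(pats)) <= 1

    def test_deterministic_under_seed(self, taxonomy):
        m = toy_manifest(taxonomy)
        a = patient_wise_split(m, rng_seed=5)
        b = patient_wise_split(m, rng_seed=5)
        assert a.records == b.records

    def test_singleton_subclass_warns_to_train(self, taxonomy):
        m = toy_manifest(taxonomy, n_patients_per_sub=4, subs=("A", "DC"))
        single = Manifest(
            m.records + (ImageRecord("lone.png", "lone", "F", "40X"),), taxonomy
        )
        with pytest.warns(UserWarning, match="single patient"):
            split = patient_wise_split(single, rng_seed=0)
        assert {r.split for r in split.records if r.patient_id == "lone"} == {"train"}

    def test_bad_fractions(self, taxonomy):
        with pytest.raises(ValueError, match="fractions"):
            patient_wise_split(toy_manifest(taxonomy), (0.5, 0.2, 0.2))


class TestCVFolds:
    def test_fold_test_sizes(self, taxonomy):
        m = toy_manifest(taxonomy, n_patients_per_sub=2, subs=("A", "F", "DC", "LC"), images_per_patient=2)
        # 8 patients is not divisible; use 10 patients across 5 subclasses
        m = toy_manifest(taxonomy, n_patients_per_sub=2, subs=("A", "F", "PT", "DC", "LC"))
        folds = make_cv_folds(m, n_folds=5, rng_seed=0)
        for f in folds:
            assert len({r.patient_id for r in f.records if r.split == "test"}) == 2

    def test_union_of_test_sets_is_all_patients(self, taxonomy):
        m = toy_manifest(taxonomy)
        folds = make_cv_folds(m, n_folds=5, rng_seed=1)
        union = set()
        for f in folds:
            test_pats = {r.patient_id for r in f.records if r.split == "test"}
            assert not (union & test_pats)  # partition: no overlap
            union |= test_pats
        assert union == set(m.patients())

    def test_stratified_within_one(self, taxonomy):
        m = toy_manifest(taxonomy, n_patients_per_sub=5)
        folds = make_cv_folds(m, n_folds=5, rng_seed=2)
        for f in folds:
            pat_split = {r.patient_id: r.split for r in f.records}
            pat_sub = {r.patient_id: r.subclass for r in f.records}
            for sub in taxonomy.subclasses:
                n_test = sum(
                    1 for p, s in pat_split.items() if s == "test" and pat_sub[p] == sub
                )
                assert abs(n_test - 1) <= 1

    def test_too_many_folds(self, taxonomy):
        m = toy_manifest(taxonomy, n_patients_per_sub=1, subs=("A", "DC"))
        with pytest.raises(ValueError, match="exceeds patient count"):
            make_cv_folds(m, n_folds=5)


class TestLeakageAudit:
    def test_clean_passes(self, taxonomy):
        m = patient_wise_split(toy_manifest(taxonomy), rng_seed=0)
        train_rec = next(r for r in m.records if r.split == "train")
        aug = Manifest(
            m.records
            + (
                ImageRecord(
                    "aug0.png",
                    train_rec.patient_id,
                    train_rec.subclass,
                    "40X",
                    split="train",
                    augmented_from=train_rec.path,
                ),
            ),
            taxonomy,
        )
        audit_no_leakage(aug, m)

    def test_leak_detected(self, taxonomy):
        m = patient_wise_split(toy_manifest(taxonomy), rng_seed=0)
        test_rec = next(r for r in m.records if r.split == "test")
        aug = Manifest(
            m.records
            + (
                ImageRecord(
                    "aug0.png",
                    test_rec.patient_id,
                    test_rec.subclass,
                    "40X",
                    split="train",
                    augmented_from=test_rec.path,
                ),
            ),
            taxonomy,
        )
        with pytest.raises(ValueError, match="leakage"):
            audit_no_leakage(aug, m)
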