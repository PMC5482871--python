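"""Patient-level and image-level recognition rates.

Two conventions are computed from a set of per-image predictions:

* patient score: the fraction of one patient's images classified correctly;
  the patient recognition rate is the unweighted mean of patient scores,
* image recognition rate: the fraction of all images classified correctly,
  ignoring patient grouping.

A confusion matrix and per-magnification breakdowns round out the report;
cross-validation summaries aggregate reports as "mean +/- sd".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hiercls.hierarchy import Taxonomy

__all__ = [
    "PredictionRecord",
    "PredictionSet",
    "MetricsReport",
    "patient_score",
    "patient_recognition_rate",
    "image_recognition_rate",
    "confusion_matrix",
    "compute_report",
    "cross_validation_summary",
]


@dataclass(frozen=True)
class PredictionRecord:
    patient_id: str
    true_subclass: str
    predicted_subclass: str
    magnification: str = "40X"


@dataclass(frozen=True)
class PredictionSet:
    """Non-empty list of per-image predictions."""

    records: tuple[PredictionRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValueError("empty prediction set")

    def __len__(self) -> int:
        return len(self.records)

    def patients(self) -> list[str]:
        seen = dict.fromkeys(r.patient_id for r in self.records)
        return list(seen)

    def filter_magnification(self, magnification: str) -> "PredictionSet":
        sub = [r for r in self.records if r.magnification == magnification]
        return PredictionSet(tuple(sub))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "true": [r.true_subclass for r in self.records],
                "predicted": [r.predicted_subclass for r in self.records],
                "magnification": [r.magnification for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictionSet":
        return cls(
            tuple(
                PredictionRecord(
                    str(row.patient_id), str(row.true), str(row.predicted), str(row.magnification)
                )
                for row in df.itertuples()
            )
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def patient_score(preds: PredictionSet, patient_id: str) -> float:
    """Fraction of this patient's images classified correctly."""
    recs = [r for r in preds.records if r.patient_id == patient_id]
    if not recs:
        raise KeyError(f"unknown patient: {patient_id!r}")
    correct = sum(r.true_subclass == r.predicted_subclass for r in recs)
    return correct / len(recs)


def patient_recognition_rate(preds: PredictionSet) -> float:
    """Unweighted mean of patient scores over all patients."""
    pats = preds.patients()
    return float(np.mean([patient_score(preds, p) for p in pats]))


def image_recognition_rate(preds: PredictionSet) -> float:
    """Fraction of all images classified correctly, ignoring patients."""
    correct = sum(r.true_subclass == r.predicted_subclass for r in preds.records)
    return correct / len(preds)


def confusion_matrix(preds: PredictionSet, taxonomy: Taxonomy) -> np.ndarray:
    """k x k count matrix, rows = true subclass, columns = predicted."""
    order = {c: i for i, c in enumerate(taxonomy.subclasses)}
    k = taxonomy.k
    cm = np.zeros((k, k), dtype=int)
    for r in preds.records:
        cm[order[taxonomy.canonical(r.true_subclass)], order[taxonomy.canonical(r.predicted_subclass)]] += 1
    return cm


@dataclass
class MetricsReport:
    patient_scores: dict[str, float]
    patient_recognition_rate: float
    image_recognition_rate: float
    confusion: np.ndarray
    class_order: tuple[str, ...]
    per_magnification: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_scores": self.patient_scores,
            "patient_recognition_rate": self.patient_recognition_rate,
            "image_recognition_rate": self.image_recognition_rate,
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "per_magnification": self.per_magnification,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def format_table(self) -> str:
        lines = [
            f"patient recognition rate: {self.patient_recognition_rate:.4f}",
            f"image recognition rate:   {self.image_recognition_rate:.4f}",
        ]
        for mag in sorted(self.per_magnification):
            m = self.per_magnification[mag]
            lines.append(
                f"  {mag:>5}: patient {m['patient_recognition_rate']:.4f}"
                f"  image {m['image_recognition_rate']:.4f}"
            )
        return "\n".join(lines)


def compute_report(preds: PredictionSet, taxonomy: Taxonomy) -> MetricsReport:
    """Full metrics report: global rates, confusion, per-magnification."""
    per_mag: dict[str, dict[str, float]] = {}
    for mag in sorted({r.magnification for r in preds.records}):
        sub = preds.filter_magnification(mag)
        per_mag[mag] = {
            "patient_recognition_rate": patient_recognition_rate(sub),
            "image_recognition_rate": image_recognition_rate(sub),
        }
    return MetricsReport(
        patient_scores={p: patient_score(preds, p) for p in preds.patients()},
        patient_recognition_rate=patient_recognition_rate(preds),
        image_recognition_rate=image_recognition_rate(preds),
        confusion=confusion_matrix(preds, taxonomy),
        class_order=taxonomy.subclasses,
        per_magnification=per_mag,
    )


def cross_validation_summary(
    reports: Sequence[MetricsReport], ddof: int = 1
) -> dict[str, dict[str, float]]:
    """Mean and standard deviation of each rate across folds.

    Uses the sample (n-1) standard deviation by default; returns
    ``{metric: {"mean": ..., "sd": ..., "formatted": "m +/- s"}}``.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 folds to summarize")
    out = {}
    for name in ("patient_recognition_rate", "image_recognition_rate"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=ddof))
        out[name] = {"mean": mean, "sd": sd, "formatted": f"{mean:.4f} ± {sd:.4f}"}
    return out
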