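"""Patient-wise detection metrics.

The cohort annotates exactly one lesion per patient and contains no
lesion-free patients, so only true positives and false negatives are
measurable at the patient level: a patient counts as detected (TP) when any
annotated slice has a detection overlapping the ground-truth box, otherwise
the patient is a false negative.  Accuracy is ``100 * TP / (TP + FN)``.
Detections on unannotated slices cannot be validated (the lesion may simply
be unannotated there); they are ignored by every metric and only tallied
informationally.

Matching is IoU-first: on each annotated slice the matched detection is the
one with maximal IoU against the ground-truth box (ties broken by higher
score).  Per patient this yields

* a per-slice IoU profile (0 where nothing overlaps),
* the maximum IoU over slices and the score of that best detection,
* the count of annotated slices with no overlapping detection (FN slices).

Cohort metrics come in two variants, mirroring the usual reporting: ``all``
averages over every patient, with FN patients contributing zeros to the
IoU/score metrics; ``IoU > 0`` averages only over TP patients (and, within a
patient, the slice-level IoU average restricts to overlapping slices).
All reported averages are on the percent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Box2D

__all__ = [
    "Detection",
    "PatientEval",
    "CohortMetrics",
    "iou",
    "evaluate_patient",
    "cohort_metrics",
    "aggregate_folds",
    "load_detections_csv",
    "write_detections_csv",
]

#: metric fields aggregated across folds
METRIC_FIELDS = (
    "tp_count",
    "fn_count",
    "accuracy_pct",
    "avg_iou_all",
    "avg_iou_pos",
    "avg_score_all",
    "avg_score_pos",
    "avg_max_iou_all",
    "avg_max_iou_pos",
    "avg_score_at_max_iou_all",
    "avg_score_at_max_iou_pos",
    "fn_slices_total",
)


@dataclass(frozen=True)
class Detection:
    """One predicted box on one slice, with a classifier score in [0, 1]."""

    slice_index: int
    box: Box2D
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


def iou(a: Box2D, b: Box2D) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    inter_h = min(a.row_max, b.row_max) - max(a.row_min, b.row_min)
    inter_w = min(a.col_max, b.col_max) - max(a.col_min, b.col_min)
    if inter_h <= 0 or inter_w <= 0:
        return 0.0
    inter = inter_h * inter_w
    return inter / (a.area + b.area - inter)


@dataclass
class PatientEval:
    """Per-patient evaluation of detections against the single annotation."""

    patient_id: str
    per_slice_iou: list[float]
    per_slice_score: list[float]  # scores of matched detections on IoU>0 slices
    max_iou: float
    score_at_max_iou: float
    is_tp: bool
    fn_slice_count: int
    fp_slice_count: int = 0  # informational: unannotated slices with detections

    @property
    def iou_mean_all(self) -> float:
        """Mean IoU over every annotated slice (zeros included)."""
        return float(np.mean(self.per_slice_iou))

    @property
    def iou_mean_pos(self) -> float:
        """Mean IoU over overlapping slices only; 0 for an FN patient."""
        pos = [v for v in self.per_slice_iou if v > 0]
        return float(np.mean(pos)) if pos else 0.0

    @property
    def score_mean(self) -> float:
        """Mean score of matched detections; 0 for an FN patient."""
        return float(np.mean(self.per_slice_score)) if self.per_slice_score else 0.0


@dataclass
class CohortMetrics:
    """Cohort-level detection metrics; averages are on the percent scale."""

    n_patients: int
    tp_count: int
    fn_count: int
    accuracy_pct: float
    avg_iou_all: float
    avg_iou_pos: float
    avg_score_all: float
    avg_score_pos: float
    avg_max_iou_all: float
    avg_max_iou_pos: float
    avg_score_at_max_iou_all: float
    avg_score_at_max_iou_pos: float
    fn_slices_total: int
    fp_slices_total: int = 0
    no_tp_patients: bool = False  # degenerate: pos-variants reported as 0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("n_patients",) + METRIC_FIELDS}


def evaluate_patient(
    patient_id: str,
    annotation,
    detections: list[Detection],
    tp_iou_threshold: float = 0.0,
) -> PatientEval:
    """Score one patient's detections against its annotation.

    On each annotated slice the detection with maximal IoU (ties -> higher
    score) is matched; slices with no detection, or whose best IoU is 0,
    contribute IoU 0 and count as FN slices.  The patient is TP iff its best
    per-slice IoU exceeds ``tp_iou_threshold`` (strictly; default 0, i.e.
    any overlap anywhere counts as detected).
    """
    by_slice: dict[int, list[Detection]] = {}
    for d in detections:
        by_slice.setdefault(d.slice_index, []).append(d)

    gt = annotation.box
    per_slice_iou: list[float] = []
    per_slice_score: list[float] = []
    max_iou = 0.0
    score_at_max = 0.0
    fn_slices = 0
    for s in annotation.slice_indices:
        cands = by_slice.get(s, [])
        best_iou, best_score = 0.0, 0.0
        for d in cands:
            v = iou(gt, d.box)
            if v > best_iou or (v == best_iou and v > 0 and d.score > best_score):
                best_iou, best_score = v, d.score
        per_slice_iou.append(best_iou)
        if best_iou > 0:
            per_slice_score.append(best_score)
            if best_iou > max_iou or (best_iou == max_iou and best_score > score_at_max):
                max_iou, score_at_max = best_iou, best_score
        else:
            fn_slices += 1

    annotated = set(annotation.slice_indices)
    fp_slices = sum(1 for s in by_slice if s not in annotated)
    return PatientEval(
        patient_id=patient_id,
        per_slice_iou=per_slice_iou,
        per_slice_score=per_slice_score,
        max_iou=max_iou,
        score_at_max_iou=score_at_max,
        is_tp=max_iou > tp_iou_threshold,
        fn_slice_count=fn_slices,
        fp_slice_count=fp_slices,
    )


def cohort_metrics(evals: list[PatientEval]) -> CohortMetrics:
    """Aggregate per-patient evaluations into cohort detection metrics.

    ``all`` variants average over every patient with FN patients contributing
    zeros; ``IoU > 0`` variants average over TP patients only.  If the cohort
    has no TP patient the pos-variants are reported as 0 and flagged.
    """
    if not evals:
        raise ValueError("cohort_metrics requires at least one patient")
    n = len(evals)
    tp = [e for e in evals if e.is_tp]
    tp_count = len(tp)
    fn_count = n - tp_count

    def pct_mean(values: list[float]) -> float:
        return float(100.0 * np.mean(values)) if values else 0.0

    return CohortMetrics(
        n_patients=n,
        tp_count=tp_count,
        fn_count=fn_count,
        accuracy_pct=100.0 * tp_count / n,
        avg_iou_all=pct_mean([e.iou_mean_all for e in evals]),
        avg_iou_pos=pct_mean([e.iou_mean_pos for e in tp]),
        avg_score_all=pct_mean([e.score_mean for e in evals]),
        avg_score_pos=pct_mean([e.score_mean for e in tp]),
        avg_max_iou_all=pct_mean([e.max_iou for e in evals]),
        avg_max_iou_pos=pct_mean([e.max_iou for e in tp]),
        avg_score_at_max_iou_all=pct_mean([e.score_at_max_iou for e in evals]),
        avg_score_at_max_iou_pos=pct_mean([e.score_at_max_iou for e in tp]),
        fn_slices_total=sum(e.fn_slice_count for e in evals),
        fp_slices_total=sum(e.fp_slice_count for e in evals),
        no_tp_patients=tp_count == 0,
    )


def aggregate_folds(
    per_fold: list[CohortMetrics],
) -> dict[str, tuple[float, float]]:
    """Cross-fold mean and sample standard deviation (n-1) of each metric."""
    if len(per_fold) < 2:
        raise ValueError("aggregate_folds requires at least 2 folds")
    out: dict[str, tuple[float, float]] = {}
    for f in METRIC_FIELDS:
        vals = np.array([getattr(m, f) for m in per_fold], dtype=float)
        out[f] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def load_detections_csv(path) -> dict[str, list[Detection]]:
    """Read detections grouped by patient.

    Columns: patient_id, slice_index (0-based), xmin, ymin, xmax, ymax
    (1-based inclusive VOC pixel coordinates; x = column, y = row), score.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    out: dict[str, list[Detection]] = {}
    for row in df.itertuples(index=False):
        box = Box2D(
            row_min=int(row.ymin) - 1,
            col_min=int(row.xmin) - 1,
            row_max=int(row.ymax),
            col_max=int(row.xmax),
        )
        out.setdefault(str(row.patient_id), []).append(
            Detection(slice_index=int(row.slice_index), box=box, score=float(row.score))
        )
    return out


def write_detections_csv(path, detections: dict[str, list[Detection]]) -> None:
    """Inverse of :func:`load_detections_csv` (same VOC 1-based dialect)."""
    rows = []
    for pid, dets in detections.items():
        for d in dets:
            rows.append(
                {
                    "patient_id": pid,
                    "slice_index": d.slice_index,
                    "xmin": d.box.col_min + 1,
                    "ymin": d.box.row_min + 1,
                    "xmax": d.box.col_max,
                    "ymax": d.box.row_max,
                    "score": round(d.score, 6),
                }
            )
    pd.DataFrame(
        rows,
        columns=["patient_id", "slice_index", "xmin", "ymin", "xmax", "ymax", "score"],
    ).to_csv(path, index=False)
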