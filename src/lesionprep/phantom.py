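"""Synthetic phantom cohorts with the statistical structure of a real
breast-MRI lesion dataset.

Each phantom patient carries 5-6 square MRI-like series of one of three
sizes (320/448/512 px, weighted as in the source cohort: 33/261/628 cases)
and exactly one lesion.  The lesion is a 3D superellipsoid: its through-slice
profile is ellipsoidal, so the in-plane cross-section is maximal at the
central slice and shrinks toward the extremities of the slice range, while
the in-plane shape is a rounded rectangle (superellipse, exponent 8) so the
central cross-section nearly fills its tight bounding box.  The single
annotation rectangle tightly bounds the central cross-section — exactly the
geometry that makes edge slices "loose" and motivates funneling selection.

Tumor slice counts are drawn from the full empirical histogram of the source
cohort (support 2-131, mode around 12-13 slices, 922 patients total weight).

Image payloads are deliberately simple: Gaussian background noise plus a
brighter lesion.  No MRI physics (coil profiles, bias fields, contrast
kinetics) is simulated; the phantoms exercise geometry and bookkeeping, not
intensity modelling.

A parametric synthetic detector (:class:`DetectorModel`) turns the ground
truth into detections: per-patient misses with probability ``p_miss_patient``
(for calibrating expected patient-wise FN counts), per-slice detections with
probability ``p_detect_slice``, Gaussian localization jitter, and a clipped
Gaussian score model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import Detection
from .types import Annotation3D, Box2D

__all__ = [
    "TABLE_SLICE_COUNT_WEIGHTS",
    "IMAGE_SIZE_WEIGHTS",
    "PhantomSpec",
    "PhantomPatient",
    "PhantomCohort",
    "DetectorModel",
    "generate_cohort",
    "generate_detections",
]

#: empirical histogram of tumor slice counts (slice count -> patient count)
TABLE_SLICE_COUNT_WEIGHTS: dict[int, int] = {
    2: 1, 3: 4, 4: 8, 5: 3, 6: 10, 7: 15, 8: 19, 9: 27, 10: 24, 11: 38,
    12: 43, 13: 44, 14: 35, 15: 36, 16: 33, 17: 34, 18: 39, 19: 26, 20: 26,
    21: 30, 22: 32, 23: 19, 24: 23, 25: 24, 26: 21, 27: 23, 28: 18, 29: 14,
    30: 8, 31: 17, 32: 17, 33: 12, 34: 11, 35: 12, 36: 4, 37: 9, 38: 10,
    39: 7, 40: 4, 41: 4, 42: 7, 43: 8, 44: 6, 45: 4, 46: 10, 47: 6, 48: 3,
    49: 6, 50: 4, 51: 7, 52: 4, 53: 4, 54: 4, 55: 3, 56: 4, 57: 3, 58: 1,
    59: 2, 60: 1, 62: 2, 63: 3, 64: 3, 65: 3, 66: 3, 67: 1, 68: 1, 69: 5,
    70: 1, 71: 1, 72: 1, 73: 1, 74: 2, 75: 1, 76: 1, 77: 1, 79: 1, 80: 1,
    81: 3, 82: 4, 85: 1, 89: 1, 90: 1, 95: 1, 96: 1, 97: 1, 102: 1, 108: 2,
    111: 1, 119: 1, 131: 1,
}

#: image sizes weighted by case counts of the source cohort
IMAGE_SIZE_WEIGHTS: dict[int, int] = {320: 33, 448: 261, 512: 628}

#: in-plane superellipse exponent; high enough that the central cross-section
#: fills >= 90% of its tight box after pixelation
SHAPE_EXPONENT = 8


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort-level generation parameters (defaults emulate the source data)."""

    n_patients: int = 20
    seed: int = 0
    image_size_weights: dict[int, int] = field(
        default_factory=lambda: dict(IMAGE_SIZE_WEIGHTS)
    )
    slice_count_weights: dict[int, int] = field(
        default_factory=lambda: dict(TABLE_SLICE_COUNT_WEIGHTS)
    )
    semi_axes_range: tuple[int, int] = (20, 48)  # in-plane, pixels
    n_series_range: tuple[int, int] = (5, 6)
    fraction_fat_suppressed: float = 0.6
    stack_pad_range: tuple[int, int] = (4, 16)  # non-tumor slices around range
    other_series_slices: tuple[int, int] = (3, 8)
    background: float = 30.0
    lesion_intensity: float = 200.0
    noise_sigma: float = 8.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(w <= 0 for w in self.slice_count_weights.values()):
            raise ValueError("slice-count weights must be positive")
        if not all(2 <= n <= 131 for n in self.slice_count_weights):
            raise ValueError("slice-count support must lie within [2, 131]")
        lo, hi = self.semi_axes_range
        if not 2 <= lo <= hi:
            raise ValueError(f"bad semi_axes_range {self.semi_axes_range}")
        if hi > min(self.image_size_weights) // 3:
            raise ValueError("lesion semi-axes too large for the smallest frame")


@dataclass
class PhantomPatient:
    """Ground truth of one generated patient."""

    patient_id: str
    image_size: int
    annotation: Annotation3D  # internal 0-based half-open convention
    annotated_series_id: str
    series_ids: list[str]
    fat_suppressed: dict[str, bool]
    n_stack: int  # slices in the annotated series
    center: tuple[float, float]  # lesion center (row, col)
    semi_axes: tuple[float, float]  # in-plane, at the central slice
    per_slice_box: dict[int, Box2D]  # tight per-slice lesion bounds
    per_slice_fill: dict[int, float]  # mask area / annotation-box area


@dataclass
class PhantomCohort:
    spec: PhantomSpec
    patients: list[PhantomPatient]
    root: Path | None = None  # where images/CSVs were written, if they were

    @property
    def annotation_csv(self) -> Path:
        if self.root is None:
            raise ValueError("cohort was generated without writing to disk")
        return self.root / "annotations.csv"


def _slice_profile(n_tumor: int) -> list[float]:
    """In-plane scale factor per tumor slice: ellipsoidal through-slice decay.

    Slice i of the range sits at t = (i - center)/(n/2); scale = sqrt(1-t^2),
    strictly positive on every slice of the range.
    """
    cz = (n_tumor - 1) / 2.0
    rz = n_tumor / 2.0
    return [
        float(np.sqrt(max(0.0, 1.0 - ((i - cz) / rz) ** 2)))
        for i in range(n_tumor)
    ]


def _superellipse_crop(
    size: int, center: tuple[float, float], semi: tuple[float, float]
) -> tuple[np.ndarray, int, int]:
    """Boolean lesion mask on a tight local window.

    Returns ``(mask, row0, col0)``: the mask covers rows ``row0 .. row0 +
    mask.shape[0]`` of the full frame.  Computing on a window keeps cohort
    generation cheap for large frames.
    """
    cr, cc = center
    ar, ac = max(semi[0], 0.7), max(semi[1], 0.7)  # never an empty mask
    row0 = max(0, int(np.floor(cr - ar)))
    row1 = min(size, int(np.ceil(cr + ar)) + 1)
    col0 = max(0, int(np.floor(cc - ac)))
    col1 = min(size, int(np.ceil(cc + ac)) + 1)
    r = np.arange(row0, row1)[:, None]
    c = np.arange(col0, col1)[None, :]
    mask = (
        np.abs((r - cr) / ar) ** SHAPE_EXPONENT
        + np.abs((c - cc) / ac) ** SHAPE_EXPONENT
    ) <= 1.0
    if not mask.any():  # sub-pixel lesion: keep a single center pixel
        mask[int(round(cr)) - row0, int(round(cc)) - col0] = True
    return mask, row0, col0


def _tight_box(mask: np.ndarray, row0: int = 0, col0: int = 0) -> Box2D:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return Box2D(
        row_min=row0 + int(rows[0]),
        col_min=col0 + int(cols[0]),
        row_max=row0 + int(rows[-1]) + 1,
        col_max=col0 + int(cols[-1]) + 1,
    )


def _weighted_choice(rng: np.random.Generator, weights: dict[int, int], k: int):
    keys = np.array(sorted(weights))
    w = np.array([weights[int(x)] for x in keys], dtype=float)
    return keys[rng.choice(len(keys), size=k, p=w / w.sum())]


def generate_cohort(
    spec: PhantomSpec,
    out_dir: str | Path | None = None,
    emit: str = "png",
) -> PhantomCohort:
    """Generate a phantom cohort; optionally write images + CSV sidecars.

    With ``out_dir`` set, the on-disk layout is the ingest dialect:
    ``<out>/<patient>/<series>/slice_NNNN.png`` (or minimal DICOM files with
    ``emit='dicom'``), ``<out>/annotations.csv`` (1-based inclusive
    coordinates) and ``<out>/series.csv`` (scan options; ``FS`` marks fat
    suppression).  Fully deterministic for a fixed spec (seeded); runs twice
    produce byte-identical CSVs.
    """
    if emit not in ("png", "dicom"):
        raise ValueError(f"unknown emit mode {emit!r}")
    rng = np.random.default_rng(spec.seed)
    sizes = _weighted_choice(rng, spec.image_size_weights, spec.n_patients)
    slice_counts = _weighted_choice(rng, spec.slice_count_weights, spec.n_patients)

    patients: list[PhantomPatient] = []
    for p in range(spec.n_patients):
        pid = f"P{p:04d}"
        size = int(sizes[p])
        n_tumor = int(slice_counts[p])
        lo, hi = spec.semi_axes_range
        hi = min(hi, size // 3)
        semi = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        margin_r, margin_c = semi[0] + 4, semi[1] + 4
        center = (
            float(rng.uniform(margin_r, size - margin_r)),
            float(rng.uniform(margin_c, size - margin_c)),
        )
        pad_before = int(rng.integers(*spec.stack_pad_range, endpoint=True))
        pad_after = int(rng.integers(*spec.stack_pad_range, endpoint=True))
        n_stack = pad_before + n_tumor + pad_after
        slice_start = pad_before
        slice_end = pad_before + n_tumor - 1

        profile = _slice_profile(n_tumor)
        per_slice_box: dict[int, Box2D] = {}
        mask_area: dict[int, int] = {}
        for j, scale in enumerate(profile):
            s = slice_start + j
            m, r0, c0 = _superellipse_crop(
                size, center, (semi[0] * scale, semi[1] * scale)
            )
            per_slice_box[s] = _tight_box(m, r0, c0)
            mask_area[s] = int(m.sum())
        # the single 3D annotation tightly bounds the largest cross-section
        ann_box = Box2D(
            row_min=min(b.row_min for b in per_slice_box.values()),
            col_min=min(b.col_min for b in per_slice_box.values()),
            row_max=max(b.row_max for b in per_slice_box.values()),
            col_max=max(b.col_max for b in per_slice_box.values()),
        )
        per_slice_fill = {
            s: mask_area[s] / ann_box.area for s in per_slice_box
        }
        annotation = Annotation3D(
            box=ann_box, slice_start=slice_start, slice_end=slice_end
        )

        n_series = int(rng.integers(*spec.n_series_range, endpoint=True))
        series_ids = [f"S{k}" for k in range(n_series)]
        annotated_sid = series_ids[int(rng.integers(n_series))]
        fat = {
            sid: bool(rng.random() < spec.fraction_fat_suppressed)
            for sid in series_ids
        }
        fat[annotated_sid] = True  # the annotated series is always usable

        patients.append(
            PhantomPatient(
                patient_id=pid,
                image_size=size,
                annotation=annotation,
                annotated_series_id=annotated_sid,
                series_ids=series_ids,
                fat_suppressed=fat,
                n_stack=n_stack,
                center=center,
                semi_axes=semi,
                per_slice_box=per_slice_box,
                per_slice_fill=per_slice_fill,
            )
        )

    cohort = PhantomCohort(spec=spec, patients=patients)
    if out_dir is not None:
        cohort.root = Path(out_dir)
        _write_cohort(cohort, rng, emit)
    return cohort


def _render_slice(
    patient: PhantomPatient, slice_index: int, spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    size = patient.image_size
    img = spec.background + rng.normal(0.0, spec.noise_sigma, (size, size))
    ann = patient.annotation
    if ann.slice_start <= slice_index <= ann.slice_end:
        j = slice_index - ann.slice_start
        scale = _slice_profile(ann.n_slices)[j]
        m, r0, c0 = _superellipse_crop(
            size,
            patient.center,
            (patient.semi_axes[0] * scale, patient.semi_axes[1] * scale),
        )
        window = img[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]]
        window[m] = spec.lesion_intensity + rng.normal(
            0.0, spec.noise_sigma, int(m.sum())
        )
    return np.clip(img, 0, 255).astype(np.uint8)


def _write_dicom_slice(
    path: Path, pixels: np.ndarray, patient_id: str, series_id: str,
    instance_number: int, fat_suppressed: bool,
) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.PatientID = patient_id
    ds.SeriesDescription = series_id
    ds.Modality = "MR"
    ds.ScanOptions = "FS" if fat_suppressed else "PER"
    ds.InstanceNumber = instance_number
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _write_cohort(
    cohort: PhantomCohort, rng: np.random.Generator, emit: str
) -> None:
    from PIL import Image

    root = cohort.root
    assert root is not None
    root.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    ann_rows, series_rows = [], []
    for pt in cohort.patients:
        for sid in pt.series_ids:
            series_rows.append(
                {
                    "patient_id": pt.patient_id,
                    "series_id": sid,
                    "scan_options": "FS" if pt.fat_suppressed[sid] else "PER",
                }
            )
            sdir = root / pt.patient_id / sid
            sdir.mkdir(parents=True, exist_ok=True)
            if sid == pt.annotated_series_id:
                n = pt.n_stack
            else:
                n = int(rng.integers(*spec.other_series_slices, endpoint=True))
            for i in range(n):
                if sid == pt.annotated_series_id:
                    pixels = _render_slice(pt, i, spec, rng)
                else:
                    pixels = np.clip(
                        spec.background
                        + rng.normal(0, spec.noise_sigma, (pt.image_size,) * 2),
                        0,
                        255,
                    ).astype(np.uint8)
                if emit == "png":
                    Image.fromarray(pixels).save(sdir / f"slice_{i + 1:04d}.png")
                else:
                    _write_dicom_slice(
                        sdir / f"slice_{i + 1:04d}.dcm",
                        pixels,
                        pt.patient_id,
                        sid,
                        i + 1,
                        pt.fat_suppressed[sid],
                    )
        b = pt.annotation.box
        # written 1-based inclusive, the clinical-table convention
        ann_rows.append(
            {
                "patient_id": pt.patient_id,
                "series_id": pt.annotated_series_id,
                "start_slice": pt.annotation.slice_start + 1,
                "end_slice": pt.annotation.slice_end + 1,
                "start_row": b.row_min + 1,
                "end_row": b.row_max,
                "start_col": b.col_min + 1,
                "end_col": b.col_max,
            }
        )
    pd.DataFrame(ann_rows).to_csv(root / "annotations.csv", index=False)
    pd.DataFrame(series_rows).to_csv(root / "series.csv", index=False)


@dataclass(frozen=True)
class DetectorModel:
    """Parametric synthetic detector over phantom ground truth.

    ``p_miss_patient`` misses a whole patient (no detections on annotated
    slices) — the dial for expected patient-wise FN counts.  Otherwise each
    tumor slice is detected with probability
    ``p_detect_slice * fill^detect_area_exponent`` (fill = cross-section
    area over annotation-box area; exponent 0 means area-independent).  A
    detected slice emits the tight per-slice lesion box, jittered by
    ``jitter_px`` (Gaussian, rounded), with a clipped-Gaussian score.
    """

    p_miss_patient: float = 0.0
    p_detect_slice: float = 1.0
    detect_area_exponent: float = 0.0
    jitter_px: float = 0.0
    score_loc: float = 0.85
    score_scale: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.p_miss_patient, self.p_detect_slice):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")


def generate_detections(
    cohort: PhantomCohort, model: DetectorModel, seed: int = 0
) -> dict[str, list[Detection]]:
    """Simulate detector output on every annotated slice of the cohort."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[Detection]] = {}
    for pt in cohort.patients:
        dets: list[Detection] = []
        missed = rng.random() < model.p_miss_patient
        for s in pt.annotation.slice_indices:
            p = model.p_detect_slice * (
                pt.per_slice_fill[s] ** model.detect_area_exponent
            )
            if missed or rng.random() >= p:
                continue
            box = pt.per_slice_box[s]
            if model.jitter_px > 0:
                dr, dc = np.rint(rng.normal(0, model.jitter_px, 2)).astype(int)
                size = pt.image_size
                dr = int(np.clip(dr, -box.row_min, size - box.row_max))
                dc = int(np.clip(dc, -box.col_min, size - box.col_max))
                box = Box2D(
                    box.row_min + dr, box.col_min + dc,
                    box.row_max + dr, box.col_max + dc,
                )
            score = float(np.clip(rng.normal(model.score_loc, model.score_scale), 0, 1))
            dets.append(Detection(slice_index=s, box=box, score=score))
        out[pt.patient_id] = dets
    return out
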