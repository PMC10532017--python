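"""Cohort ingestion: annotation table + on-disk slice stacks -> PatientCase list.

Two storage modes share one directory layout
(``image_root/<patient_id>/<series_id>/<slice files>``):

* ``png`` — phantom/lightweight mode.  Slices are PNG files whose names embed
  an instance number (``slice_0007.png``); per-series scan options live in a
  sidecar ``series.csv`` (columns patient_id, series_id, scan_options).
* ``dicom`` — slices are DICOM files; instance numbers come from
  InstanceNumber (0020,0013) and scan options from ScanOptions (0018,0022).

The annotation table is a flat CSV, one row per patient, in the 1-based
inclusive convention clinical annotations typically use::

    patient_id, series_id, start_slice, end_slice,
    start_row, end_row, start_col, end_col

``series_id`` names the series the annotation geometry applies to.  All
coordinates are converted exactly once, here, to the internal 0-based
half-open convention.

Only fat-suppressed series carry valid annotations in this kind of dataset;
:func:`filter_fat_suppressed` drops the rest (a scan-options token match,
``FS`` by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Annotation3D, Box2D, PatientCase, SeriesMeta, SliceRecord

__all__ = [
    "LoadError",
    "load_cohort",
    "filter_fat_suppressed",
    "iter_slice_records",
    "load_slice_pixels",
    "DEFAULT_FS_REGEX",
]

logger = logging.getLogger(__name__)

DEFAULT_FS_REGEX = r"FS"

ANNOTATION_COLUMNS = [
    "patient_id",
    "series_id",
    "start_slice",
    "end_slice",
    "start_row",
    "end_row",
    "start_col",
    "end_col",
]


@dataclass(frozen=True)
class LoadError:
    """Record of a patient that could not be loaded (cohort load continues)."""

    patient_id: str
    reason: str


def _instance_key_png(path: Path) -> tuple[int, str]:
    m = re.search(r"(\d+)\D*$", path.stem)
    return (int(m.group(1)) if m else 0, path.name)


def _list_series_png(series_dir: Path) -> list[str]:
    files = [p for p in series_dir.iterdir() if p.suffix.lower() == ".png"]
    return [p.name for p in sorted(files, key=_instance_key_png)]


def _list_series_dicom(series_dir: Path) -> tuple[list[str], str]:
    import pydicom

    keyed = []
    scan_options = ""
    for p in sorted(series_dir.iterdir()):
        if p.suffix.lower() not in (".dcm", ".dicom", ""):
            continue
        ds = pydicom.dcmread(p, stop_before_pixels=True)
        inst = int(getattr(ds, "InstanceNumber", 0) or 0)
        opts = getattr(ds, "ScanOptions", "") or ""
        if isinstance(opts, (list, tuple)):
            opts = "\\".join(str(o) for o in opts)
        scan_options = scan_options or str(opts)
        keyed.append((inst, p.name))
    return [name for _, name in sorted(keyed)], scan_options


def parse_annotation_row(row) -> Annotation3D:
    # 1-based inclusive -> 0-based half-open happens here and only here
    return Annotation3D(
        box=Box2D(
            row_min=int(row.start_row) - 1,
            col_min=int(row.start_col) - 1,
            row_max=int(row.end_row),
            col_max=int(row.end_col),
        ),
        slice_start=int(row.start_slice) - 1,
        slice_end=int(row.end_slice) - 1,
    )


def _image_size_of(path: Path) -> int:
    if path.suffix.lower() == ".png":
        from PIL import Image

        with Image.open(path) as im:
            w, h = im.size
    else:
        import pydicom

        ds = pydicom.dcmread(path, stop_before_pixels=True)
        h, w = int(ds.Rows), int(ds.Columns)
    if h != w:
        raise ValueError(f"non-square slice {path}: {h}x{w}")
    return h


def load_cohort(
    annotation_csv: str | Path,
    image_root: str | Path,
    mode: str = "auto",
    fat_suppression_regex: str = DEFAULT_FS_REGEX,
    errors: list[LoadError] | None = None,
) -> list[PatientCase]:
    """Read the annotation table and assemble one PatientCase per row.

    A missing patient directory produces a :class:`LoadError` (appended to
    ``errors`` if given, logged otherwise) and the load continues; a
    malformed annotation row is a hard error naming the row.  Slice order
    within each series is a pure function of instance numbers, so a shuffled
    directory listing yields the identical stack.
    """
    annotation_csv = Path(annotation_csv)
    image_root = Path(image_root)
    df = pd.read_csv(annotation_csv, dtype={"patient_id": str, "series_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate annotation row for patient {dup}")

    if mode == "auto":
        mode = "dicom" if any(image_root.rglob("*.dcm")) else "png"
    if mode not in ("png", "dicom"):
        raise ValueError(f"unknown mode {mode!r}")

    series_opts: dict[tuple[str, str], str] = {}
    if mode == "png":
        sidecar = image_root / "series.csv"
        if sidecar.exists():
            sdf = pd.read_csv(
                sidecar, dtype={"patient_id": str, "series_id": str}
            ).fillna({"scan_options": ""})
            for r in sdf.itertuples(index=False):
                series_opts[(r.patient_id, r.series_id)] = str(r.scan_options or "")

    fs_pattern = re.compile(fat_suppression_regex, re.IGNORECASE)
    cases: list[PatientCase] = []
    for i, row in enumerate(df.itertuples(index=False)):
        pid = str(row.patient_id)
        try:
            annotation = parse_annotation_row(row)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed annotation row {i} (patient {pid}): {exc}")

        patient_dir = image_root / pid
        if not patient_dir.is_dir():
            err = LoadError(pid, f"missing patient directory {patient_dir}")
            if errors is not None:
                errors.append(err)
            logger.warning("skipping patient %s: %s", pid, err.reason)
            continue

        series_list: list[SeriesMeta] = []
        for sdir in sorted(p for p in patient_dir.iterdir() if p.is_dir()):
            sid = sdir.name
            if mode == "png":
                order = _list_series_png(sdir)
                opts = series_opts.get((pid, sid), "")
            else:
                order, opts = _list_series_dicom(sdir)
            if not order:
                continue
            series_list.append(
                SeriesMeta(
                    series_id=sid,
                    fat_suppressed=bool(fs_pattern.search(opts)),
                    slice_order=order,
                )
            )
        target = next(
            (s for s in series_list if s.series_id == str(row.series_id)), None
        )
        if target is None:
            err = LoadError(pid, f"annotated series {row.series_id} not found")
            if errors is not None:
                errors.append(err)
            logger.warning("skipping patient %s: %s", pid, err.reason)
            continue

        size = _image_size_of(patient_dir / target.series_id / target.slice_order[0])
        cases.append(
            PatientCase(
                patient_id=pid,
                image_size=size,
                series=series_list,
                annotation=annotation,
                annotated_series_id=str(row.series_id),
            )
        )
    return cases


def filter_fat_suppressed(case: PatientCase) -> PatientCase:
    """Drop series without fat suppression; the annotation is untouched.

    If no series survives, the patient is flagged unusable (downstream
    stages exclude it) rather than erased from the cohort.
    """
    kept = [s for s in case.series if s.fat_suppressed]
    usable = bool(kept) and any(
        s.series_id == case.annotated_series_id for s in kept
    )
    if not usable:
        logger.warning(
            "patient %s: no usable fat-suppressed series after filtering",
            case.patient_id,
        )
        # keep original series so the case still validates; mark unusable
        return PatientCase(
            patient_id=case.patient_id,
            image_size=case.image_size,
            series=case.series,
            annotation=case.annotation,
            annotated_series_id=case.annotated_series_id,
            usable=False,
        )
    return PatientCase(
        patient_id=case.patient_id,
        image_size=case.image_size,
        series=kept,
        annotation=case.annotation,
        annotated_series_id=case.annotated_series_id,
        usable=case.usable,
    )


def iter_slice_records(case: PatientCase, image_root: str | Path) -> list[SliceRecord]:
    """Slice records of the annotated series, in stack order."""
    image_root = Path(image_root)
    target = case.annotated_series()
    if target is None:
        raise ValueError(
            f"patient {case.patient_id}: annotated series "
            f"{case.annotated_series_id} absent"
        )
    return [
        SliceRecord(
            patient_id=case.patient_id,
            series_id=target.series_id,
            slice_index=i,
            path=str(image_root / case.patient_id / target.series_id / name),
            image_size=case.image_size,
        )
        for i, name in enumerate(target.slice_order)
    ]


def load_slice_pixels(path: str | Path) -> np.ndarray:
    """Pixel array of one slice file (PNG or DICOM), as a 2D numpy array."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        with Image.open(path) as im:
            return np.asarray(im)
    import pydicom

    return pydicom.dcmread(path).pixel_array
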