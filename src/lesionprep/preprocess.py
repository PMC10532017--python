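"""Resolution normalization, box rescaling, Pascal VOC export, dataset assembly.

Patient stacks come in three square sizes (320/448/512 px); the detector
consumes one size, 448 by default, so every slice is resized and the
annotation rectangle rescaled with it.  Each exported training slice gets a
Pascal-VOC-dialect XML annotation (1-based inclusive ``bndbox`` coordinates,
``x`` = column, ``y`` = row).  Dataset assembly enforces the patient-wise
contract: training patients contribute only their funnel-kept tumor slices,
test patients contribute every slice of the annotated series, and no slice
of any patient may appear in both subsets.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import iter_slice_records, load_slice_pixels
from .selection import SelectionResult
from .types import Box2D, PatientCase, SliceRecord

__all__ = [
    "ResizeSpec",
    "rescale_box",
    "resize_slice",
    "write_slice_annotation",
    "read_slice_annotation",
    "assemble_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResizeSpec:
    original_size: int
    target_size: int = 448

    def __post_init__(self) -> None:
        if self.original_size <= 0 or self.target_size <= 0:
            raise ValueError("sizes must be positive")

    @property
    def scale(self) -> float:
        return self.target_size / self.original_size


def _round_half_up(x: float) -> int:
    # round .5 away from zero; coordinates are non-negative here
    return int(np.floor(x + 0.5))


def rescale_box(box: Box2D, spec: ResizeSpec) -> Box2D:
    """Map a box from the original frame to the target frame.

    Coordinates scale by ``target/original``, round to nearest (.5 up) and
    clamp to the frame.  A box degenerate after rounding is widened by one
    pixel on the max side (min side if at the frame edge) with a warning.
    """
    box.validate_for(spec.original_size)
    s = spec.scale
    t = spec.target_size
    rmin = min(_round_half_up(box.row_min * s), t)
    rmax = min(_round_half_up(box.row_max * s), t)
    cmin = min(_round_half_up(box.col_min * s), t)
    cmax = min(_round_half_up(box.col_max * s), t)
    if rmin == rmax:
        logger.warning("degenerate row extent after rescale of %s; widening", box)
        if rmax < t:
            rmax += 1
        else:
            rmin -= 1
    if cmin == cmax:
        logger.warning("degenerate col extent after rescale of %s; widening", box)
        if cmax < t:
            cmax += 1
        else:
            cmin -= 1
    return Box2D(row_min=rmin, col_min=cmin, row_max=rmax, col_max=cmax)


def resize_slice(pixels: np.ndarray, spec: ResizeSpec) -> np.ndarray:
    """Bilinear resize of a square slice to the target size.

    Identity when sizes already agree (bitwise).  Integer input comes back
    in the same dtype.
    """
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected square 2D input, got shape {pixels.shape}")
    if pixels.shape[0] != spec.original_size:
        raise ValueError(
            f"input size {pixels.shape[0]} != spec original {spec.original_size}"
        )
    if spec.original_size == spec.target_size:
        return pixels
    from skimage.transform import resize

    out = resize(
        pixels.astype(np.float64),
        (spec.target_size, spec.target_size),
        order=1,
        mode="edge",
        anti_aliasing=spec.target_size < spec.original_size,
        preserve_range=True,
    )
    if np.issubdtype(pixels.dtype, np.integer):
        info = np.iinfo(pixels.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(pixels.dtype)
    return out.astype(pixels.dtype)


def write_slice_annotation(
    path: str | Path,
    filename: str,
    image_size: int,
    boxes: list[Box2D],
    label: str = "tumor",
) -> None:
    """Write one Pascal-VOC-dialect XML annotation file.

    Internal 0-based half-open boxes become VOC 1-based inclusive:
    ``xmin = col_min + 1``, ``xmax = col_max`` (likewise rows/y), so a
    read-back parses to the identical boxes.
    """
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(image_size)
    ET.SubElement(size, "height").text = str(image_size)
    ET.SubElement(size, "depth").text = "1"
    for box in boxes:
        box.validate_for(image_size)
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(box.col_min + 1)
        ET.SubElement(bnd, "ymin").text = str(box.row_min + 1)
        ET.SubElement(bnd, "xmax").text = str(box.col_max)
        ET.SubElement(bnd, "ymax").text = str(box.row_max)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def read_slice_annotation(path: str | Path) -> tuple[str, int, list[Box2D]]:
    """Parse a VOC XML back to (filename, image_size, boxes) — inverse of write."""
    root = ET.parse(path).getroot()
    filename = root.findtext("filename", "")
    image_size = int(root.findtext("size/width", "0"))
    boxes = []
    for obj in root.findall("object"):
        bnd = obj.find("bndbox")
        boxes.append(
            Box2D(
                row_min=int(bnd.findtext("ymin")) - 1,
                col_min=int(bnd.findtext("xmin")) - 1,
                row_max=int(bnd.findtext("ymax")),
                col_max=int(bnd.findtext("xmax")),
            )
        )
    return filename, image_size, boxes


def _export_slice(
    record: SliceRecord, spec: ResizeSpec, out_path: Path
) -> None:
    from PIL import Image

    pixels = load_slice_pixels(record.path)
    resized = resize_slice(pixels, spec)
    if resized.dtype != np.uint8:
        lo, hi = float(resized.min()), float(resized.max())
        resized = (
            np.zeros_like(resized, dtype=np.uint8)
            if hi == lo
            else (255 * (resized - lo) / (hi - lo)).astype(np.uint8)
        )
    Image.fromarray(resized).save(out_path)


def assemble_dataset(
    cohort: list[PatientCase],
    split: tuple[list[str], list[str]],
    selections: dict[str, SelectionResult],
    image_root: str | Path,
    out_dir: str | Path,
    target_size: int = 448,
    label: str = "tumor",
) -> pd.DataFrame:
    """Build the final train/test directory layout and return its manifest.

    ``train/`` receives the funnel-kept tumor slices of training patients —
    resized PNG plus a VOC XML holding the rescaled box.  ``test/`` receives
    every slice of each test patient's annotated series, images only (the
    inference stage must see the whole stack).  Patients flagged unusable
    are skipped.  A patient in both subsets is a hard error.

    The manifest (also written to ``out_dir/manifest.csv``, with the split
    declaration in ``out_dir/split.csv``) lists one row per exported image:
    patient_id, series_id, slice_index, subset, image, annotation.
    """
    train_ids, test_ids = split
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"patients in both subsets: {sorted(overlap)}")
    by_id = {c.patient_id: c for c in cohort}

    out_dir = Path(out_dir)
    image_root = Path(image_root)
    for sub in ("train", "test"):
        (out_dir / sub / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "train" / "annotations").mkdir(parents=True, exist_ok=True)

    rows = []
    for pid in train_ids:
        case = by_id.get(pid)
        if case is None or not case.usable:
            continue
        sel = selections[pid]
        spec = ResizeSpec(original_size=case.image_size, target_size=target_size)
        box = rescale_box(case.annotation.box, spec)
        records = iter_slice_records(case, image_root)
        for idx in sel.kept_range:
            rec = records[idx]
            stem = f"{pid}_{rec.series_id}_{idx:04d}"
            img_path = out_dir / "train" / "images" / f"{stem}.png"
            xml_path = out_dir / "train" / "annotations" / f"{stem}.xml"
            _export_slice(rec, spec, img_path)
            write_slice_annotation(xml_path, f"{stem}.png", target_size, [box], label)
            rows.append(
                {
                    "patient_id": pid,
                    "series_id": rec.series_id,
                    "slice_index": idx,
                    "subset": "train",
                    "image": str(img_path.relative_to(out_dir)),
                    "annotation": str(xml_path.relative_to(out_dir)),
                }
            )
    for pid in test_ids:
        case = by_id.get(pid)
        if case is None or not case.usable:
            continue
        spec = ResizeSpec(original_size=case.image_size, target_size=target_size)
        for rec in iter_slice_records(case, image_root):
            stem = f"{pid}_{rec.series_id}_{rec.slice_index:04d}"
            img_path = out_dir / "test" / "images" / f"{stem}.png"
            _export_slice(rec, spec, img_path)
            rows.append(
                {
                    "patient_id": pid,
                    "series_id": rec.series_id,
                    "slice_index": rec.slice_index,
                    "subset": "test",
                    "image": str(img_path.relative_to(out_dir)),
                    "annotation": "",
                }
            )

    manifest = pd.DataFrame(
        rows,
        columns=["patient_id", "series_id", "slice_index", "subset", "image", "annotation"],
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    split_df = pd.DataFrame(
        [{"patient_id": p, "subset": "train"} for p in train_ids]
        + [{"patient_id": p, "subset": "test"} for p in test_ids]
    )
    split_df.to_csv(out_dir / "split.csv", index=False)
    logger.info(
        "assembled dataset: %d train images, %d test images",
        (manifest["subset"] == "train").sum(),
        (manifest["subset"] == "test").sum(),
    )
    return manifest
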