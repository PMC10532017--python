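"""Core domain types for patient cohorts of annotated MRI slice stacks.

A cohort is a list of :class:`PatientCase` objects.  Each patient carries a
square slice stack (one of several MRI series) and exactly one lesion
annotation: a single 2D rectangle paired with an inclusive slice range — the
same rectangle applies to every slice in the range, so edge slices where the
lesion cross-section has shrunk are "loose".

Coordinate conventions
----------------------
Internally every box is 0-based and half-open: ``row_max``/``col_max`` are one
past the last lesion pixel.  Clinical annotation tables are typically 1-based
inclusive; conversion happens exactly once, at load time
(:func:`lesionprep.ingest.load_cohort`).  Pascal VOC XML output is 1-based
inclusive per the VOC convention (:mod:`lesionprep.preprocess`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


VALID_IMAGE_SIZES = (320, 448, 512)


@dataclass(frozen=True)
class Box2D:
    """Axis-aligned rectangle in pixel coordinates, 0-based half-open."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_min < self.row_max):
            raise ValueError(f"invalid row bounds: [{self.row_min}, {self.row_max})")
        if not (0 <= self.col_min < self.col_max):
            raise ValueError(f"invalid col bounds: [{self.col_min}, {self.col_max})")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def area(self) -> int:
        return self.height * self.width

    def validate_for(self, image_size: int) -> None:
        """Raise if the box exceeds a square frame of ``image_size`` pixels."""
        if self.row_max > image_size or self.col_max > image_size:
            raise ValueError(
                f"box {self} exceeds {image_size}x{image_size} frame"
            )


@dataclass(frozen=True)
class Annotation3D:
    """One lesion: a 2D box plus an inclusive slice range (0-based indices).

    The rectangle tightly bounds the lesion on its central slice and is
    reused unchanged for every slice in ``[slice_start, slice_end]``.
    """

    box: Box2D
    slice_start: int
    slice_end: int

    def __post_init__(self) -> None:
        if self.slice_start < 0:
            raise ValueError(f"slice_start must be >= 0, got {self.slice_start}")
        if self.slice_end < self.slice_start:
            raise ValueError(
                f"slice_end ({self.slice_end}) < slice_start ({self.slice_start})"
            )

    @property
    def n_slices(self) -> int:
        return self.slice_end - self.slice_start + 1

    @property
    def slice_indices(self) -> range:
        return range(self.slice_start, self.slice_end + 1)


@dataclass
class SeriesMeta:
    """One MRI acquisition: an ordered slice stack with scan options."""

    series_id: str
    fat_suppressed: bool
    slice_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.slice_order)) != len(self.slice_order):
            raise ValueError(f"series {self.series_id}: duplicate slice identifiers")

    @property
    def n_slices(self) -> int:
        return len(self.slice_order)


@dataclass
class PatientCase:
    """One patient: square slice stacks of a single size plus one annotation."""

    patient_id: str
    image_size: int
    series: list[SeriesMeta]
    annotation: Annotation3D
    annotated_series_id: str
    usable: bool = True

    def __post_init__(self) -> None:
        if self.image_size not in VALID_IMAGE_SIZES:
            raise ValueError(
                f"patient {self.patient_id}: image_size {self.image_size} "
                f"not in {VALID_IMAGE_SIZES}"
            )
        self.annotation.box.validate_for(self.image_size)
        target = self.annotated_series()
        if target is not None and self.annotation.slice_end >= target.n_slices:
            raise ValueError(
                f"patient {self.patient_id}: annotation slice range "
                f"[{self.annotation.slice_start}, {self.annotation.slice_end}] "
                f"exceeds series of {target.n_slices} slices"
            )

    def annotated_series(self) -> SeriesMeta | None:
        for s in self.series:
            if s.series_id == self.annotated_series_id:
                return s
        return None


@dataclass(frozen=True)
class SliceRecord:
    """Pointer to one slice image on disk, with its position in the stack."""

    patient_id: str
    series_id: str
    slice_index: int
    path: str
    image_size: int
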