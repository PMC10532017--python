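"""Resizing, box rescaling, VOC XML round-trips and dataset assembly."""

import numpy as np
import pytest
import xml.etree.ElementTree as ET
from hypothesis import given
from hypothesis import strategies as st

from lesionprep.ingest import load_cohort
from lesionprep.preprocess import (
    ResizeSpec,
    assemble_dataset,
    read_slice_annotation,
    rescale_box,
    resize_slice,
    write_slice_annotation,
)
from lesionprep.selection import funnel_keep_count, select_training_slices
from lesionprep.types import Box2D


def test_full_frame_maps_to_full_frame():
    spec = ResizeSpec(original_size=512, target_size=448)
    assert rescale_box(Box2D(0, 0, 512, 512), spec) == Box2D(0, 0, 448, 448)


def test_same_size_rescale_is_identity():
    spec = ResizeSpec(original_size=448, target_size=448)
    box = Box2D(17, 23, 101, 250)
    assert rescale_box(box, spec) == box


def test_exact_scale_arithmetic_320_to_448():
    # scale 1.4; all products integral, so no rounding ambiguity
    spec = ResizeSpec(original_size=320, target_size=448)
    assert rescale_box(Box2D(100, 200, 200, 300), spec) == Box2D(140, 280, 280, 420)


def test_degenerate_rescale_is_widened():
    # 1-px box at scale 448/512 rounds to zero extent; must come back valid
    spec = ResizeSpec(original_size=512, target_size=448)
    out = rescale_box(Box2D(100, 100, 101, 101), spec)
    assert out.row_max > out.row_min and out.col_max > out.col_min


@given(
    rmin=st.integers(0, 318), cmin=st.integers(0, 318),
    h=st.integers(1, 100), w=st.integers(1, 100),
    sizes=st.sampled_from([(320, 448), (512, 448), (448, 320), (448, 512)]),
)
def test_rescale_round_trip_within_one_pixel(rmin, cmin, h, w, sizes):
    orig, target = sizes
    rmax, cmax = min(rmin + h, orig), min(cmin + w, orig)
    box = Box2D(rmin, cmin, rmax, cmax)
    fwd = ResizeSpec(original_size=orig, target_size=target)
    back = ResizeSpec(original_size=target, target_size=orig)
    round_tripped = rescale_box(rescale_box(box, fwd), back)
    for attr in ("row_min", "col_min", "row_max", "col_max"):
        assert abs(getattr(round_tripped, attr) - getattr(box, attr)) <= 1


def test_resize_identity_is_bitwise():
    img = np.random.default_rng(0).integers(0, 255, (448, 448)).astype(np.uint8)
    out = resize_slice(img, ResizeSpec(original_size=448, target_size=448))
    assert out is img


def test_resize_constant_image_stays_constant():
    img = np.full((512, 512), 77, dtype=np.uint8)
    out = resize_slice(img, ResizeSpec(original_size=512, target_size=448))
    assert out.shape == (448, 448)
    assert np.all(out == 77)


def test_resize_rejects_non_square():
    with pytest.raises(ValueError):
        resize_slice(np.zeros((100, 200)), ResizeSpec(200, 448))


def test_resized_disk_scales_radius_and_keeps_centroid():
    """Geometry oracle: a disk of radius r resized by s has area ~ (r*s)^2*pi
    and its centroid moves by at most one pixel (in scaled coordinates)."""
    size, target = 512, 448
    r, cr, cc = 60, 200.0, 300.0
    y, x = np.mgrid[0:size, 0:size]
    img = (((y - cr) ** 2 + (x - cc) ** 2) <= r**2).astype(np.uint8) * 255
    out = resize_slice(img, ResizeSpec(original_size=size, target_size=target))
    mask = out > 127
    s = target / size
    assert mask.sum() == pytest.approx(np.pi * (r * s) ** 2, rel=0.02)
    ys, xs = np.nonzero(mask)
    assert ys.mean() == pytest.approx(cr * s, abs=1.0)
    assert xs.mean() == pytest.approx(cc * s, abs=1.0)


def test_voc_xml_coordinate_convention(tmp_path):
    path = tmp_path / "a.xml"
    write_slice_annotation(path, "a.png", 448, [Box2D(10, 20, 30, 40)])
    bnd = ET.parse(path).getroot().find("object/bndbox")
    assert int(bnd.findtext("xmin")) == 21
    assert int(bnd.findtext("ymin")) == 11
    assert int(bnd.findtext("xmax")) == 40
    assert int(bnd.findtext("ymax")) == 30


def test_voc_xml_round_trip_and_order(tmp_path):
    boxes = [Box2D(1, 2, 3, 4), Box2D(100, 200, 300, 400)]
    path = tmp_path / "two.xml"
    write_slice_annotation(path, "two.png", 448, boxes)
    fname, size, back = read_slice_annotation(path)
    assert (fname, size) == ("two.png", 448)
    assert back == boxes


def test_voc_xml_zero_boxes(tmp_path):
    path = tmp_path / "none.xml"
    write_slice_annotation(path, "none.png", 448, [])
    _, _, back = read_slice_annotation(path)
    assert back == []
    assert len(ET.parse(path).getroot().findall("object")) == 0


@pytest.fixture(scope="module")
def assembled(phantom_dir, tmp_path_factory):
    cohort = load_cohort(phantom_dir.annotation_csv, phantom_dir.root)
    ids = sorted(c.patient_id for c in cohort)
    train_ids, test_ids = ids[:-2], ids[-2:]
    selections = {
        c.patient_id: select_training_slices(c.annotation)
        for c in cohort if c.patient_id in train_ids
    }
    out = tmp_path_factory.mktemp("dataset")
    manifest = assemble_dataset(
        cohort, (train_ids, test_ids), selections, phantom_dir.root, out
    )
    return cohort, train_ids, test_ids, manifest, out


def test_assembled_counts_match_selection_arithmetic(assembled):
    cohort, train_ids, test_ids, manifest, _ = assembled
    by_id = {c.patient_id: c for c in cohort}
    expect_train = sum(
        funnel_keep_count(by_id[p].annotation.n_slices) for p in train_ids
    )
    expect_test = sum(
        by_id[p].annotated_series().n_slices for p in test_ids
    )
    assert (manifest["subset"] == "train").sum() == expect_train
    assert (manifest["subset"] == "test").sum() == expect_test
    # every train image has an annotation, no test image does
    train_rows = manifest[manifest["subset"] == "train"]
    assert (train_rows["annotation"] != "").all()
    assert (manifest.loc[manifest["subset"] == "test", "annotation"] == "").all()


def test_assembled_no_cross_subset_leakage(assembled):
    _, _, _, manifest, out = assembled
    train_p = set(manifest.loc[manifest["subset"] == "train", "patient_id"])
    test_p = set(manifest.loc[manifest["subset"] == "test", "patient_id"])
    assert not train_p & test_p
    assert not manifest["image"].duplicated().any()
    for rel in manifest["image"]:
        assert (out / rel).exists()


def test_assembled_train_xml_holds_rescaled_box(assembled):
    cohort, train_ids, _, manifest, out = assembled
    by_id = {c.patient_id: c for c in cohort}
    row = manifest[manifest["subset"] == "train"].iloc[0]
    case = by_id[row["patient_id"]]
    _, size, (box,) = read_slice_annotation(out / row["annotation"])
    assert size == 448
    expected = rescale_box(
        case.annotation.box, ResizeSpec(original_size=case.image_size)
    )
    assert box == expected


def test_overlapping_subsets_abort(assembled):
    cohort, train_ids, test_ids, _, _ = assembled
    with pytest.raises(ValueError, match="both subsets"):
        assemble_dataset(
            cohort, (train_ids, [train_ids[0]]), {}, ".", "unused"
        )
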