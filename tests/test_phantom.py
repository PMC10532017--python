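"""Phantom generator: determinism, looseness geometry, sampling distributions,
and the synthetic detector's calibration."""

import numpy as np
import pytest
from scipy import stats

from lesionprep.evaluation import cohort_metrics, evaluate_patient
from lesionprep.phantom import (
    IMAGE_SIZE_WEIGHTS,
    TABLE_SLICE_COUNT_WEIGHTS,
    DetectorModel,
    PhantomSpec,
    generate_cohort,
    generate_detections,
)
from lesionprep.selection import select_training_slices


def test_generation_is_deterministic_on_disk(tmp_path):
    spec = PhantomSpec(
        n_patients=3, seed=21, stack_pad_range=(2, 3), other_series_slices=(2, 2)
    )
    generate_cohort(spec, tmp_path / "a")
    generate_cohort(spec, tmp_path / "b")
    assert (tmp_path / "a/annotations.csv").read_bytes() == (
        tmp_path / "b/annotations.csv"
    ).read_bytes()
    assert (tmp_path / "a/series.csv").read_bytes() == (
        tmp_path / "b/series.csv"
    ).read_bytes()


def test_lesion_cross_section_funnels_toward_extremities():
    # force 9-slice lesions so the profile is comparable across patients
    spec = PhantomSpec(n_patients=5, seed=2, slice_count_weights={9: 1})
    cohort = generate_cohort(spec)
    for pt in cohort.patients:
        fills = [pt.per_slice_fill[s] for s in pt.annotation.slice_indices]
        assert max(fills) >= 0.90          # central slice nearly fills its box
        assert fills[0] < 0.5 and fills[-1] < 0.5   # edge slices are loose
        mid = len(fills) // 2
        assert fills[mid] == max(fills)
        # symmetric unimodal profile: non-decreasing to center
        assert all(a <= b for a, b in zip(fills[: mid + 1], fills[1 : mid + 1]))


def test_annotation_box_bounds_every_cross_section():
    cohort = generate_cohort(PhantomSpec(n_patients=10, seed=4))
    for pt in cohort.patients:
        ann = pt.annotation.box
        for s, box in pt.per_slice_box.items():
            assert ann.row_min <= box.row_min and box.row_max <= ann.row_max
            assert ann.col_min <= box.col_min and box.col_max <= ann.col_max
        assert ann == pt.per_slice_box[
            max(pt.per_slice_fill, key=pt.per_slice_fill.get)
        ] or ann.area >= max(b.area for b in pt.per_slice_box.values())


def test_slice_count_histogram_matches_weights():
    cohort = generate_cohort(PhantomSpec(n_patients=1000, seed=8))
    counts = [p.annotation.n_slices for p in cohort.patients]
    assert 2 <= min(counts) and max(counts) <= 131
    # chi-square against the configured weights, banded to keep expected
    # counts reasonable
    bands = [(2, 16), (17, 31), (32, 46), (47, 62), (63, 77), (79, 131)]
    total_w = sum(TABLE_SLICE_COUNT_WEIGHTS.values())
    expected = np.array(
        [
            sum(w for n, w in TABLE_SLICE_COUNT_WEIGHTS.items() if lo <= n <= hi)
            / total_w
            for lo, hi in bands
        ]
    ) * len(counts)
    observed = np.array(
        [sum(1 for c in counts if lo <= c <= hi) for lo, hi in bands]
    )
    assert stats.chisquare(observed, expected).pvalue > 1e-3


def test_image_size_frequencies_match_weights():
    cohort = generate_cohort(PhantomSpec(n_patients=1000, seed=9))
    sizes = [p.image_size for p in cohort.patients]
    total = sum(IMAGE_SIZE_WEIGHTS.values())
    for size, w in IMAGE_SIZE_WEIGHTS.items():
        frac = sizes.count(size) / len(sizes)
        assert frac == pytest.approx(w / total, abs=0.05)


def test_infeasible_lesion_size_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(semi_axes_range=(20, 200))


def _evaluate(cohort, detections):
    return cohort_metrics(
        [
            evaluate_patient(p.patient_id, p.annotation,
                             detections.get(p.patient_id, []))
            for p in cohort.patients
        ]
    )


def test_perfect_detector_scores_perfectly(memory_cohort):
    dets = generate_detections(memory_cohort, DetectorModel(), seed=0)
    m = _evaluate(memory_cohort, dets)
    assert m.accuracy_pct == 100.0
    assert m.avg_max_iou_all == pytest.approx(100.0)
    assert m.fn_slices_total == 0


def test_blind_detector_misses_everyone(memory_cohort):
    dets = generate_detections(
        memory_cohort, DetectorModel(p_detect_slice=0.0), seed=0
    )
    m = _evaluate(memory_cohort, dets)
    assert m.accuracy_pct == 0.0
    assert m.fn_count == len(memory_cohort.patients)


def test_patient_miss_rate_is_binomially_calibrated(memory_cohort):
    """With per-patient miss probability q the FN count over many seeds must
    sit inside the 95% binomial envelope of n_trials * q."""
    q = 0.25
    model = DetectorModel(p_miss_patient=q)
    n = len(memory_cohort.patients)
    total_fn = 0
    n_seeds = 20
    for seed in range(n_seeds):
        dets = generate_detections(memory_cohort, model, seed=seed)
        total_fn += _evaluate(memory_cohort, dets).fn_count
    lo, hi = stats.binom.interval(0.95, n * n_seeds, q)
    assert lo <= total_fn <= hi


def test_jittered_detector_degrades_iou_but_not_detection(memory_cohort):
    dets = generate_detections(
        memory_cohort, DetectorModel(jitter_px=4.0), seed=1
    )
    m = _evaluate(memory_cohort, dets)
    assert m.accuracy_pct == 100.0
    assert m.avg_max_iou_all < 100.0


def test_selection_removes_lowest_fill_slices(memory_cohort):
    """Funneling drops exactly the slices whose cross-section fill fraction
    is lowest: every removed slice fills its box no more than any kept one."""
    for pt in memory_cohort.patients:
        sel = select_training_slices(pt.annotation)
        kept = set(sel.kept_range)
        removed = set(pt.annotation.slice_indices) - kept
        if not removed:
            continue
        assert max(pt.per_slice_fill[s] for s in removed) <= min(
            pt.per_slice_fill[s] for s in kept
        ) + 1e-12
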