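"""Patient-wise detection metrics: IoU oracle, matching, cohort aggregation."""

import itertools

import numpy as np
import pytest

from lesionprep.evaluation import (
    Detection,
    PatientEval,
    aggregate_folds,
    cohort_metrics,
    evaluate_patient,
    iou,
    load_detections_csv,
    write_detections_csv,
)
from lesionprep.types import Annotation3D, Box2D

# the ten printed per-fold accuracies and FN counts the aggregation
# statistics must reproduce
FOLD_ACCURACIES = [96.74, 95.65, 97.83, 93.48, 96.74, 94.57, 93.48, 91.30, 94.57, 90.22]
FOLD_FN_COUNTS = [3, 4, 2, 6, 3, 5, 6, 8, 5, 9]


def pixel_iou(a: Box2D, b: Box2D, size: int = 8) -> float:
    """Independent IoU oracle: rasterize both boxes and count pixels."""
    ga = np.zeros((size, size), dtype=bool)
    gb = np.zeros((size, size), dtype=bool)
    ga[a.row_min : a.row_max, a.col_min : a.col_max] = True
    gb[b.row_min : b.row_max, b.col_min : b.col_max] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union


def all_boxes(size: int):
    for rmin, rmax in itertools.combinations(range(size + 1), 2):
        for cmin, cmax in itertools.combinations(range(size + 1), 2):
            yield Box2D(rmin, cmin, rmax, cmax)


def test_iou_simple_cases():
    a = Box2D(0, 0, 2, 2)
    assert iou(a, a) == 1.0
    assert iou(a, Box2D(4, 4, 6, 6)) == 0.0
    # unit squares offset by half a side: intersection 1/2 of a square -> 1/3
    assert iou(Box2D(0, 0, 2, 2), Box2D(0, 1, 2, 3)) == pytest.approx(1 / 3)


def test_iou_matches_pixel_oracle_exhaustively():
    boxes = list(all_boxes(4))
    for a in boxes:
        for b in boxes:
            assert iou(a, b) == pytest.approx(pixel_iou(a, b)), (a, b)


def _ann(n_slices=3, start=0):
    return Annotation3D(
        box=Box2D(0, 0, 10, 10), slice_start=start, slice_end=start + n_slices - 1
    )


def test_perfect_detections():
    ann = _ann(3)
    dets = [Detection(s, ann.box, 0.9) for s in ann.slice_indices]
    ev = evaluate_patient("p", ann, dets)
    assert ev.is_tp and ev.max_iou == 1.0
    assert ev.score_at_max_iou == pytest.approx(0.9)
    assert ev.fn_slice_count == 0
    assert ev.per_slice_iou == [1.0, 1.0, 1.0]


def test_no_detections_is_fn_patient():
    ann = _ann(4)
    ev = evaluate_patient("p", ann, [])
    assert not ev.is_tp
    assert ev.max_iou == 0.0
    assert ev.fn_slice_count == 4


def test_known_per_slice_iou_profile():
    # gt 10x10; detections engineered for per-slice IoUs {0, 0.4, 0.7}
    ann = _ann(3)
    dets = [
        Detection(0, Box2D(20, 20, 30, 30), 0.9),  # disjoint -> 0
        Detection(1, Box2D(0, 0, 4, 10), 0.8),     # 40/100 -> 0.4
        Detection(2, Box2D(0, 0, 7, 10), 0.7),     # 70/100 -> 0.7
    ]
    ev = evaluate_patient("p", ann, dets)
    assert ev.per_slice_iou == pytest.approx([0.0, 0.4, 0.7])
    assert ev.max_iou == pytest.approx(0.7)
    assert ev.score_at_max_iou == pytest.approx(0.7)
    assert ev.iou_mean_all == pytest.approx(1.1 / 3)
    assert ev.iou_mean_pos == pytest.approx(0.55)
    assert ev.fn_slice_count == 1


def test_matching_agrees_with_brute_force_enumeration():
    """With <= 3 candidates per slice, exhaustive search for the
    (max IoU, then max score) detection must agree with the matcher."""
    rng = np.random.default_rng(42)
    gt = Box2D(2, 2, 6, 6)
    ann = Annotation3D(box=gt, slice_start=0, slice_end=0)
    for _ in range(200):
        n = int(rng.integers(1, 4))
        cands = []
        for _ in range(n):
            r0, c0 = rng.integers(0, 7, 2)
            h, w = rng.integers(1, 4, 2)
            cands.append(
                Detection(0, Box2D(int(r0), int(c0), int(r0 + h), int(c0 + w)),
                          float(rng.integers(0, 100) / 100))
            )
        best = max(cands, key=lambda d: (iou(gt, d.box), d.score))
        ev = evaluate_patient("p", ann, cands)
        assert ev.max_iou == pytest.approx(iou(gt, best.box))
        if ev.max_iou > 0:
            assert ev.score_at_max_iou == pytest.approx(best.score)


def test_zero_iou_detection_changes_nothing():
    ann = _ann(3)
    dets = [Detection(1, Box2D(0, 0, 4, 10), 0.8)]
    base = cohort_metrics([evaluate_patient("p", ann, dets)])
    noisy = dets + [Detection(0, Box2D(50, 50, 60, 60), 0.99),
                    Detection(1, Box2D(90, 90, 99, 99), 0.99)]
    after = cohort_metrics([evaluate_patient("p", ann, noisy)])
    for k, v in base.as_dict().items():
        assert after.as_dict()[k] == pytest.approx(v), k


def _fake_evals(tp: int, fn: int) -> list[PatientEval]:
    evals = []
    for i in range(tp):
        evals.append(PatientEval(f"tp{i}", [0.5], [0.8], 0.5, 0.8, True, 0))
    for i in range(fn):
        evals.append(PatientEval(f"fn{i}", [0.0], [], 0.0, 0.0, False, 1))
    return evals


@pytest.mark.parametrize(
    "tp,fn,expected",
    [(53, 3, 94.64), (54, 2, 96.43), (90, 2, 97.83)],
)
def test_cohort_accuracy_values(tp, fn, expected):
    m = cohort_metrics(_fake_evals(tp, fn))
    assert round(m.accuracy_pct, 2) == expected
    assert m.tp_count == tp and m.fn_count == fn
    # accuracy recomputed from per-patient booleans agrees
    assert m.accuracy_pct == pytest.approx(100 * tp / (tp + fn))


def test_all_fn_cohort_is_degenerate_but_defined():
    m = cohort_metrics(_fake_evals(0, 5))
    assert m.accuracy_pct == 0.0
    assert m.no_tp_patients
    assert m.avg_iou_pos == 0.0 and m.avg_score_pos == 0.0


def test_pos_variants_dominate_all_variants():
    m = cohort_metrics(_fake_evals(7, 3))
    assert m.avg_iou_pos >= m.avg_iou_all
    assert m.avg_max_iou_pos >= m.avg_max_iou_all


def test_cohort_metrics_requires_patients():
    with pytest.raises(ValueError):
        cohort_metrics([])


def _metrics_with(accuracy: float, fn: int):
    # fold of 92 patients with the stated accuracy / FN count
    tp = 92 - fn
    m = cohort_metrics(_fake_evals(tp, fn))
    assert round(m.accuracy_pct, 2) == accuracy
    return m


def test_fold_aggregation_reproduces_published_mean_and_sample_std():
    folds = [
        _metrics_with(acc, fn)
        for acc, fn in zip(FOLD_ACCURACIES, FOLD_FN_COUNTS)
    ]
    agg = aggregate_folds(folds)
    mean_acc, std_acc = agg["accuracy_pct"]
    assert round(mean_acc, 2) == 94.46
    assert round(std_acc, 2) == 2.43
    # the population (n-denominator) std would be 2.30 — the sample
    # (n-1) estimator is the one that reproduces the reference value
    pop_std = float(np.std(FOLD_ACCURACIES))
    assert round(pop_std, 2) == 2.30 != round(std_acc, 2)
    mean_fn, std_fn = agg["fn_count"]
    assert round(mean_fn, 2) == 5.10
    assert round(std_fn, 2) == 2.23


def test_identical_folds_have_zero_std():
    m = cohort_metrics(_fake_evals(9, 1))
    agg = aggregate_folds([m, m, m])
    for mean, std in agg.values():
        assert std == 0.0


def test_aggregation_needs_two_folds():
    with pytest.raises(ValueError):
        aggregate_folds([cohort_metrics(_fake_evals(1, 0))])


def test_detections_csv_round_trip(tmp_path):
    dets = {
        "pA": [Detection(3, Box2D(10, 20, 30, 40), 0.75)],
        "pB": [Detection(0, Box2D(0, 0, 5, 5), 1.0),
               Detection(1, Box2D(2, 2, 9, 9), 0.25)],
    }
    path = tmp_path / "d.csv"
    write_detections_csv(path, dets)
    back = load_detections_csv(path)
    assert back == dets
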