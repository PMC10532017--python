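"""Patient-wise evaluation of detector output.

A patient is a true positive when any annotated slice has a detection
overlapping the ground-truth box; accuracy is TP / (TP + FN).  Per patient
the matched detection on each slice is the one with maximal IoU.
"""

from lesionprep import (
    Annotation3D,
    Box2D,
    Detection,
    cohort_metrics,
    evaluate_patient,
)

gt = Annotation3D(box=Box2D(40, 40, 80, 80), slice_start=0, slice_end=2)

# detector found the lesion on 2 of 3 slices, with imperfect localization
detections = [
    Detection(slice_index=1, box=Box2D(44, 40, 84, 80), score=0.92),
    Detection(slice_index=2, box=Box2D(40, 40, 80, 80), score=0.88),
]
hit = evaluate_patient("patient_A", gt, detections)
missed = evaluate_patient("patient_B", gt, [])  # detector found nothing

m = cohort_metrics([hit, missed])
print(f"patient_A: per-slice IoU {[round(v, 3) for v in hit.per_slice_iou]}, "
      f"max IoU {hit.max_iou:.3f}, score@max {hit.score_at_max_iou:.2f}")
print(f"patient_B: false negative, {missed.fn_slice_count} missed slices")
print(f"cohort: accuracy {m.accuracy_pct:.2f}% "
      f"({m.tp_count} TP / {m.fn_count} FN), "
      f"avg max IoU (all) {m.avg_max_iou_all:.2f}%, "
      f"(IoU>0) {m.avg_max_iou_pos:.2f}%")
# 'all' averages include the FN patient as zeros; 'IoU>0' averages only
# the detected patients, so they are always at least as large.
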