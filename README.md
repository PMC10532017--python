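# lesionprep

Patient-wise preparation and evaluation toolkit for MRI lesion-detection
datasets.

Breast DCE-MRI lesion datasets are typically annotated with a single 3D
bounding box per patient: one 2D rectangle (row/column bounds) paired with an
inclusive slice range. The rectangle is sized for the lesion's largest
cross-section, so on the first and last slices of the range — where the
lesion has shrunk to a sliver — most of the box is background. Training an
object detector on those *loose-box* slices injects label noise. `lesionprep`
implements the dataset-preparation pipeline around this problem for people
building detection benchmarks from such cohorts: slice selection, resolution
normalization and annotation export, leakage-free splitting, and the
patient-wise metrics appropriate when only one lesion per patient is
annotated.

## What it computes

**Funneling slice selection.** For a lesion spanning *n* slices, keep the

```
n_keep = ceil(n · a · ln b),        a = 0.75,  b = 1.9625
```

central slices and remove the rest from the two ends of the range
(⌊R/2⌋ from the start, ⌈R/2⌉ from the end, R = n − n_keep). The asymptotic
keep fraction is a·ln b ≈ 0.5057 — large lesions lose about half their
slices — while the ceiling spares small ones (a 2-slice lesion keeps both).
Selection applies to training patients only; test patients keep every slice.

**Patient-wise splitting.** Single train/test splits and k-fold plans operate
on whole patients, never images. With n patients and k folds, each fold holds
⌊n/k⌋ patients and the n mod k leftovers join every training set (922
patients at k = 10: ten test folds of 92, train sets of 830).

**Dataset assembly.** Slices are resized to a common resolution (448×448 by
default) with boxes rescaled alongside, and each training slice gets a Pascal
VOC XML annotation. Training exports contain only the funnel-kept tumor
slices; test exports contain whole stacks.

**Evaluation.** With exactly one annotated lesion per patient and no
lesion-free patients, only patient-wise TP/FN are measurable: a patient
counts as detected when any annotated slice has an overlapping detection,
and accuracy = 100·TP/(TP+FN). Per patient the toolkit reports the per-slice
IoU profile, the maximum IoU and its detection's score, and FN slice counts;
cohort averages come in `all` (FN patients as zeros) and `IoU > 0` (detected
patients only) variants, plus cross-fold mean ± sample (n−1) standard
deviation.

**Synthetic phantoms.** A seeded generator produces cohorts with the real
data's structure — square stacks of 320/448/512 px, one superellipsoid lesion
per patient whose cross-section shrinks toward the slice-range ends (the
loose-box geometry), tumor slice counts drawn from an empirical 2–131
histogram, 5–6 series per patient with fat-suppression flags — and a
parametric synthetic detector with dialable miss rates, so the entire
pipeline is testable without any clinical data.

## Worked example

```python
from lesionprep import Annotation3D, Box2D, select_training_slices

ann = Annotation3D(box=Box2D(100, 120, 160, 200), slice_start=10, slice_end=18)
sel = select_training_slices(ann)
```

prints, via `examples/funnel_selection.py`:

```
9-slice tumor at slices 10..18 -> keep slices 12..16 (5 of 9; removed 2 from
the start, 2 from the end)
```

The 9-slice lesion keeps its 5 central slices — the ones whose cross-section
still fills most of the annotation rectangle — and drops 2 loose slices from
each end.

End to end (`examples/phantom_pipeline.py`): a 10-patient phantom cohort,
70/30 patient split, funneling on the training side, dataset export, and a
synthetic detector that finds 90% of tumor slices with 3 px localization
jitter:

```
dataset images exported: 250
test patients: 3, accuracy 100.00% (3 TP / 0 FN)
avg IoU (all slices, FN as zero): 54.81%
avg max IoU: 93.28%  avg score @ max IoU: 81.64%
```

Every test patient is detected (accuracy 100%), and the gap between the
per-slice average IoU (55%) and the max IoU (93%) is the loose-box effect:
edge slices overlap poorly even when central slices localize almost
perfectly — which is why the patient-wise max-based metrics are the
actionable ones.

The same capabilities are scriptable from the shell via the `lesionprep`
CLI (`phantom`, `select`, `folds`, `build`, `eval`, `schedule`, `run`); see
`lesionprep --help`.

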