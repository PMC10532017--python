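# Methods

## The preparation problem

The cohorts this toolkit targets annotate each patient with a single 3D
bounding box: one axis-aligned rectangle plus an inclusive slice range, the
rectangle sized for the lesion's largest cross-section. Because a lesion is
roughly ellipsoidal through-slice, its cross-section near the ends of the
range fills only a small fraction of that rectangle. Exporting every
annotated slice for detector training therefore labels large amounts of
background as "tumor" on the edge slices. The pipeline's core operation
removes those slices in a size-aware way, and the surrounding stages (series
filtering, resizing, splitting, evaluation) enforce the patient-wise
discipline that such per-patient annotations require.

## Funneling selection

For a lesion spanning `n` slices the keep count is `ceil(n · a · ln b)` with
defaults `a = 0.75`, `b = 1.9625`. Both coefficients are dimensionless
heuristics: their product `a·ln b ≈ 0.5057` is the asymptotic keep fraction,
and the ceiling guarantees at least one kept slice and spares small lesions
entirely (n = 2 keeps both slices; halving such lesions would destroy most
of their signal). The removal total `R = n − n_keep` splits as
`(floor(R/2), ceil(R/2))`: when R is odd the extra slice comes off the end
of the range. The constraint `a·ln b ≤ 1` is validated at construction —
values above 1 would "keep" more slices than exist.

Selection is count-based only; no pixel-content criterion is applied. On
phantoms this is provably equivalent to removing the lowest-fill slices
(the cross-section profile is unimodal and symmetric), and the suite checks
that rank agreement. It is applied exclusively to training patients: test
patients retain full stacks so a detector can be assessed on every slice.

## Coordinate conventions

Internally all boxes are 0-based half-open (`max` one past the last lesion
pixel), all slice indices 0-based. Conversions live at exactly two
boundaries: annotation tables and detection CSVs are 1-based inclusive (the
clinical convention) and are converted on load; Pascal VOC XML is written
1-based inclusive per the VOC standard (`xmin = col_min + 1`,
`xmax = col_max`; VOC `x` is the column axis, `y` the row axis — the image
convention). Box rescaling multiplies by `target/original`, rounds half away
from zero, clamps to the frame, and widens a degenerate (zero-extent) result
by one pixel with a warning; a rescale round-trip is within ±1 px per
coordinate. Slice resizing is bilinear — standard for MRI magnitude images;
no intensity normalization or windowing is applied.

## Ingestion

Cohorts are read from a flat annotation CSV (one row per patient, naming
the annotated series) plus per-patient series directories, in PNG mode
(phantoms; sidecar `series.csv` carries scan options) or DICOM mode
(InstanceNumber orders the stack, ties broken by filename; ScanOptions
supplies the scan-options text). Fat suppression is detected by a
case-insensitive `FS` token match on the scan-options string, overridable
by regex — the conventional encoding, though site-specific dialects exist,
hence the override. Series without fat suppression are dropped because the
annotations only apply to fat-suppressed acquisitions; a patient left with
no usable series is flagged and excluded downstream rather than deleted. A
missing patient directory is a recorded, non-fatal error; a malformed
annotation row is fatal and names the row.

## Partitioning

All splits are permutations of patient identifiers from a seeded
`numpy.random.default_rng`; the seed is stored in the plan file. The k-fold
plan deals the first `k·floor(n/k)` shuffled patients into k folds and marks
the `n mod k` leftovers REMAINDER: they join every training set and are
never tested. The alternative (distributing extras across folds) was
rejected because it makes fold sizes unequal; with 922 patients and k = 10
the rule yields the 830/92 train/test sizes used as the reference case.
Each non-remainder patient is tested exactly once.

## Evaluation

Matching is IoU-first: on each annotated slice the matched detection
maximizes IoU against the ground-truth box, ties broken by higher score
(score-first matching would make "score at max IoU" meaningless). Slices
whose best IoU is zero count as FN slices. A patient is TP when its best
per-slice IoU strictly exceeds the threshold (default 0: any overlap
anywhere counts); the threshold is exposed for stricter definitions.
Detections outside the annotated slice range cannot be validated — the
single-lesion annotation says nothing about other slices — so they are
excluded from every metric and only tallied informationally. For the same
reason precision-style metrics are out of scope.

Per-patient "average score" averages matched-detection scores (slices with
an overlapping detection); within-patient IoU averages come in an
all-slices variant (zeros included) and an overlapping-slices variant.
Cohort `all` averages span every patient with FN patients contributing
zeros; `IoU > 0` averages span TP patients only, which is why the pos
variants dominate the all variants row by row. Averages are reported on the
percent scale. Cross-fold aggregation uses the arithmetic mean and the
sample (n−1) standard deviation — the estimator that reproduces the
reference ±2.43 accuracy spread from the ten per-fold accuracies (the
population estimator gives 2.30). A cohort with no TP patient reports its
pos-variants as 0 with an explicit degeneracy flag.

## Training-schedule arithmetic

Epochs = `total_steps · batch_size / train_set_size` (one step consumes one
batch); the reference configuration 200,000 × 32 / 39,592 gives 161.65,
reported rounded to 162 (nearest — the conventional reading). The learning
rate follows pure cosine decay `base_lr · (1 + cos(π·step/total))/2` from
0.05 to exactly 0, with no warmup (configurable warmup was considered and
omitted: the reference schedule shows none). The uniform initialization
limit is `sqrt(3/fan_in)` — the scaling that keeps pre-activation variance
at 1/fan-in; the augmentation set (50% horizontal/vertical flips, 50% 90°
rotation, brightness delta ≤ 0.05, contrast factor in [0.5, 0.95]) is
implemented with exact box transforms so the geometry is verifiable:
flips and rotations preserve box area and containment, photometric jitter
leaves boxes untouched.

## Phantom generator

The generator's defaults emulate the structure of the target cohort rather
than inventing a convenient one: image sizes 320/448/512 weighted 33/261/628
by case counts; tumor slice counts drawn from the full empirical histogram
(support 2–131, mode near 12–13); 5–6 series per patient, 60% of them
fat-suppressed with the annotated series forced fat-suppressed (an annotated
patient must be usable); stacks pad the tumor range with 4–16 background
slices on each side.

Lesion geometry: a superellipsoid — ellipsoidal through-slice profile
`scale(t) = sqrt(1 − t²)` with the semi-axis chosen so every slice of the
range intersects the lesion, and an in-plane superellipse of exponent 8
(a rounded rectangle). The exponent matters: a true ellipse fills only π/4
of its tight box, whereas at exponent 8 the central cross-section fills
≥ 90% after pixelation, so the single annotation rectangle (the tight bound
of the largest cross-section) is genuinely tight centrally and loose at the
ends (edge fill ≈ scale², e.g. ~20% for a 9-slice lesion) — the geometry
the selection method exists for. In-plane semi-axes are uniform in
[20, 48] px; below ~20 px pixelation erodes the central fill guarantee.
Masks are computed on a tight local window, so generating thousands of
in-memory patients for distribution tests costs about a second.

Image payloads are monochrome uint8: Gaussian background (mean 30, σ 8)
with a brighter lesion (mean 200). No MRI physics — no coil profiles, bias
fields, contrast kinetics or anatomy — is simulated. Passing tests
therefore validate the geometry, bookkeeping and statistics of the
pipeline, not robustness to realistic MRI appearance. Output is PNG stacks
with CSV sidecars by default, or minimal DICOM files (ScanOptions,
InstanceNumber, uint8 PixelData) to exercise the DICOM ingest path.

The synthetic detector emits, per tumor slice, the tight per-slice lesion
box with optional Gaussian jitter and a clipped-Gaussian score
(N(0.85, 0.05) by default). Whole-patient misses fire with probability
`p_miss_patient`, making expected patient-wise FN counts exactly binomial —
the property the calibration tests check; per-slice detection probability
may optionally depend on cross-section fill. A perfect detector
(defaults) yields accuracy 100% and max IoU 1.0 by construction, because
the central tight box equals the annotation box.

## Pipeline

The training stage is deliberately an interface boundary: the pipeline
emits the prepared dataset and consumes detections (a CSV from an external
model, or the synthetic detector on phantom truth). Every stage is wrapped
so failures abort naming the stage, with partial outputs retained. All
randomness flows from the config seed (fold-level detector seeds are
derived as `seed + 1000 + fold`), and the resolved config is written into
the run directory; identical configs give byte-identical metrics.

## Problem sizes and numerical choices

The suite exercises cohorts of 6–20 patients on disk and up to 1000
in-memory patients for distribution checks; the selection invariants are
swept exhaustively over lesion sizes 1–10⁴; the miss-rate calibration uses
20 patients × 20 seeds against a 95% binomial envelope. The chi-square test
of the slice-count histogram bands sizes into six ranges so expected counts
stay well above the small-count regime. Degenerate inputs are defined
rather than rejected where a sensible answer exists: a 1-slice lesion keeps
its slice (below the real data's minimum of 2, allowed for robustness), a
zero-extent rescaled box is widened, an all-FN cohort reports zeroed pos
metrics with a flag.

## Known limitations

Single-lesion annotations only; no multi-lesion matching or precision/AP
metrics (unvalidatable under this annotation scheme). Phantom intensities
are not MRI-realistic, and phantom lesions are axis-aligned superellipsoids
— rank agreement between fill fraction and slice position is exact by
construction, which real lesions will not satisfy. DICOM support covers the
attributes the pipeline reads (pixel data, InstanceNumber, ScanOptions);
it is not a general DICOM conformance layer.
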