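"""Funneling slice selection on lesions of different sizes.

A lesion annotated across n slices keeps its ceil(n * 0.75 * ln 1.9625)
central slices for training; the loose-box edge slices are dropped,
floor(R/2) from the start of the range and ceil(R/2) from the end.
"""

from lesionprep import Annotation3D, Box2D, funnel_table, select_training_slices

print("n_total  remove(start,end)  keep")
for row in funnel_table(10):
    print(f"{row['n_total']:>7}  ({row['remove_start']}, {row['remove_end']})"
          f"{'':<12}{row['n_keep']:>4}")

# a 9-slice tumor occupying slices 10..18 of its series
ann = Annotation3D(box=Box2D(100, 120, 160, 200), slice_start=10, slice_end=18)
sel = select_training_slices(ann)
print(f"\n9-slice tumor at slices 10..18 -> keep slices "
      f"{sel.kept_start}..{sel.kept_end} ({sel.n_keep} of {sel.n_total}; "
      f"removed {sel.remove_start} from the start, {sel.remove_end} from the end)")
# The kept range is always contiguous and centred: the slices where the
# lesion cross-section fills most of the annotation rectangle.
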