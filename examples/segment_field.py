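"""Detect single red blood cells in a synthetic 415 nm absorbance field.

Builds a noisy 50-cell field with known ground truth, runs the full
segmentation pipeline (scale estimation, rolling-ball background, Otsu,
watershed, size filter), and scores the detections against the truth.
"""
from erythroquant import segment, synth

truth = synth.make_rbc_scene(n_cells=50, radius=8.0, snr=5, seed=2)
img, truth = synth.generate_rbc_field(truth)

radius = segment.estimate_cell_scale(img)
cells, labels = segment.segment_cells(img)
f1, err = segment.detection_f1(
    [c.centroid for c in cells], [c.center for c in truth.cells]
)

print(f"estimated cell radius: {radius:.2f} px (true 8.0)")
print(f"detected {len(cells)} of {len(truth.cells)} cells")
print(f"detection F1 = {f1:.3f}, mean centroid error = {err:.2f} px")
print("F1 of 1.0 means every cell was found once, with no false detections.")
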