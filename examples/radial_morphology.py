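"""Compare red-cell radial absorbance profiles before and after treatment.

A discocyte absorbs most 415 nm light over its thick ring and least at its
dimpled centre.  Here the "post" population carries extra central
absorbance (swollen centres); the per-bin t-tests with a Holm-Sidak family
correction localize the change to the centre band.
"""
import dataclasses

from erythroquant import radial, segment, synth


def profiles_for(center_boost, seed):
    truth = synth.make_rbc_scene(12, seed=seed, snr=10)
    truth = dataclasses.replace(
        truth,
        cells=tuple(dataclasses.replace(c, center_boost=center_boost)
                    for c in truth.cells),
    )
    img, _ = synth.generate_rbc_field(truth)
    cells, _ = segment.segment_cells(img)
    return [radial.radial_profile(img, c) for c in cells]


pre = profiles_for(center_boost=0.0, seed=21)
post = profiles_for(center_boost=0.4, seed=22)

table, center_significant = radial.compare_populations(pre, post)
center = table[table["bin_px"] <= radial.CENTER_BAND_PX]

print(table[["bin_px", "mean_diff", "p_adj", "significant"]].to_string(index=False))
print(f"\ncentre band (|r| <= {radial.CENTER_BAND_PX} px) significant: "
      f"{center_significant}")
print("A significant centre band means absorbance rose where the cell is")
print("normally thinnest - the morphological signature of central swelling.")
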