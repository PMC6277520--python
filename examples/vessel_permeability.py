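"""Quantify tracer penetration into a vessel wall.

Each intima pixel is assigned its Euclidean distance to the nearest lumen
pixel; mean fluorescence per 1-px distance bin is the penetration profile.
Ten control sections are compared against ten sections with doubled surface
intensity (a leakier wall) by a Welch t-test on per-image summaries.
"""
from erythroquant import permeability as perm, synth


def profiles(surface_intensity, seed0, n=10):
    out = []
    for k in range(n):
        truth = synth.make_annular_vessel(
            decay_length=10.0, surface_intensity=surface_intensity,
            snr=5, seed=seed0 + k,
        )
        img, truth = synth.generate_vessel_section(truth)
        out.append(perm.distance_profile(
            perm.VesselSection(img, truth.lumen_mask, truth.intima_mask)
        ))
    return out


control = profiles(1000.0, seed0=0)
treated = profiles(2000.0, seed0=100)

i0, lam, baseline = perm.fit_decay_length(control[0])
print(f"fitted decay: I0 = {i0:.0f}, lambda = {lam:.2f} px "
      f"({lam * 0.5:.2f} um at 0.5 um/px; true lambda = 10 px)")

res = perm.compare_conditions(control, treated)
print(f"Welch t = {res['test'].statistic:.2f}, "
      f"df = {res['test'].df:.1f}, p = {res['test'].pvalue:.3g}")
print(f"direction: {res['direction']}, significant: {res['significant']}")
print("lambda is the 1/e penetration depth of the tracer; a larger")
print("near-lumen mean in the treated arm indicates increased permeability.")
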