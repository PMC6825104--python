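"""Three-material differentiation of a simulated dual-energy thorax.

Generates a phantom with a known gas/tissue/blood composition, renders the
two energy volumes with 5-HU noise, calibrates the material basis from the
aorta and parasternal-muscle ROIs, and decomposes the pair. The printed
means compare recovered volume fractions with the ground truth; agreement
to a fraction of a percent shows the per-voxel solve inverts the mixing
model correctly under realistic noise.
"""

import numpy as np

import dectlung as dl

truth = dl.generate_phantom(dl.PhantomSpec(shape=(48, 64, 6), seed=0))
pair = dl.render_dect(truth)
basis = dl.calibrate_basis(
    pair, dl.RoiMask(truth.aorta_mask, "aorta"), dl.RoiMask(truth.muscle_mask, "parasternal muscle")
)
print("calibrated basis (HU at low/high energy):")
for material, coef in basis.to_dict().items():
    print(f"  {material:16s} {coef[0]:8.1f} {coef[1]:8.1f}")

fractions = dl.decompose(pair, basis, dl.RoiMask(truth.lung_mask, "lung"))
m = truth.lung_mask
for name, est, true in (
    ("gas", fractions.f_gas, truth.fractions.f_gas),
    ("soft tissue", fractions.f_tissue, truth.fractions.f_tissue),
    ("iodinated blood", fractions.f_blood, truth.fractions.f_blood),
):
    print(f"mean {name:16s} recovered {est[m].mean()*100:5.1f} %   true {true[m].mean()*100:5.1f} %")
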