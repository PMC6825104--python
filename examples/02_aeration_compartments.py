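"""Aeration compartments from the decomposed gas volume fraction.

Classifies lung voxels at the 10/50/90 % gas-fraction cut-offs (the
-100/-500/-900 HU equivalents on non-contrast scans) and prints the
volume fraction of each compartment. The dependent atelectatic mass and
the gravitational gradient of the phantom show up as nonzero atelectatic
and poorly aerated fractions.
"""

import numpy as np

import dectlung as dl

truth = dl.generate_phantom(dl.PhantomSpec(shape=(48, 64, 6), seed=0))
pair = dl.render_dect(truth)
basis = dl.calibrate_basis(
    pair, dl.RoiMask(truth.aorta_mask, "aorta"), dl.RoiMask(truth.muscle_mask, "muscle")
)
fr = dl.decompose(pair, basis, dl.RoiMask(truth.lung_mask, "lung"))

aer = dl.classify_aeration(np.nan_to_num(fr.f_gas, nan=0.0), truth.lung_mask, spacing=truth.spec.spacing)
summary = dl.compartment_fractions(aer)
for name, pct in summary.fractions_pct.items():
    print(f"{name:18s} {pct:5.1f} % of lung volume")
print(f"total lung volume  {summary.total_volume_ml:.1f} mL")
print("the four fractions partition the lung and sum to "
      f"{sum(summary.fractions_pct.values()):.1f} %")
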