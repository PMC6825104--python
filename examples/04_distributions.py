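"""Density and fraction histograms, and how alike two distributions are.

Builds the normalized 10-HU-bin density histogram of the merged volume
and the 1 %-bin gas-fraction histogram, for the whole lung and for the
central 5-mm slab, then correlates them with Pearson's r. An r close to 1
means the thin slab's voxel composition resembles the whole lung's —
the central question when a single dynamic slice stands in for the lung.
"""

import numpy as np

import dectlung as dl
from dectlung.phantom import dynamic_slice_mask

truth = dl.generate_phantom(dl.PhantomSpec(shape=(48, 64, 6), seed=0))
pair = dl.render_dect(truth)
merge = dl.merge_volumes(pair)
fr_gas = truth.fractions.f_gas
slab = dynamic_slice_mask(truth)

hu_whole = dl.density_histogram(merge.data, truth.lung_mask)
hu_slab = dl.density_histogram(merge.data, slab)
print(f"density histogram: {hu_whole.n_bins} bins, weights sum to {hu_whole.weights.sum():.9f}")
print(f"slab vs whole-lung density correlation r = {dl.distribution_correlation(hu_slab, hu_whole):.3f}")

g_whole = dl.fraction_histogram(fr_gas, truth.lung_mask)
g_slab = dl.fraction_histogram(fr_gas, slab)
print(f"slab vs whole-lung gas-fraction correlation r = {dl.distribution_correlation(g_slab, g_whole):.3f}")
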