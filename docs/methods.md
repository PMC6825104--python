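# Methods

## Three-material differentiation

Each voxel's two measured CT densities plus the unity constraint form a
3×3 linear system in the volume fractions of gas, soft tissue and
iodinated blood. The system matrix (two coefficient rows, one row of
ones) is voxel-independent, so one shared matrix inverse solves every
voxel exactly; the contract is the mathematical solution, not a
particular iterative scheme. Identifiability rests on iodinated blood
attenuating differently at the two energies — if two materials have
nearly identical energy signatures the matrix becomes ill-conditioned,
so a basis with condition number ≥ 1e6 is rejected with an error naming
the closest material pair rather than silently amplifying noise.

Raw solutions sum to one exactly (the constraint is part of the system)
but can leave [0, 1] under noise. The projection policy clips negative
fractions to zero and renormalizes to unit sum, which preserves the
partition needed by downstream segmentation; the Euclidean distance
moved is stored per voxel so users can audit how much the projection
altered the data. The unprojected solve is exposed separately
(`decompose_raw`) because the raw estimator is unbiased under additive
HU noise while the projected one is not near the simplex boundary — the
test suite checks unbiasedness on the raw maps.

Calibration takes ROI means: aorta → iodinated blood, parasternal
muscle → soft tissue, gas fixed at −1000 HU at both energies. The merge
volume defaults to 70 % weight on the high-energy image and 30 % on the
low; which energy carries the 70 % is a convention, configurable via
`merge_weight_high` (and `--merge-weight-high` on the CLI).

## Aeration compartments

Classification uses the gas volume fraction, not the contrast-enhanced
HU, so iodinated blood cannot masquerade as atelectasis. Cut-offs are
gas fractions 0.10 / 0.50 / 0.90; on a contrast-free gas/soft-tissue
mixture these correspond to −100 / −500 / −900 HU
(`noncontrast_equivalent_hu`), and the suite verifies the two routes
classify identically in that case. The printed ranges of the four
compartments overlap at their endpoints, so a single boundary convention
is fixed for determinism: [0, 0.10) atelectasis, [0.10, 0.50) poor,
[0.50, 0.90] normal, (0.90, 1] overdistended. Anatomical exclusion of
heart, aorta, oesophagus, azygos vein and inferior vena cava on real
scans is represented by the user-supplied analysis mask; the package
performs no organ segmentation.

## Dynamic frame classification

Per-frame gas volume is the masked slab volume times the mean gas
fraction. "Within 30 % of the minimum or maximum" is read as within 30 %
of the min-to-max *range* measured from each extreme: the
value-referenced alternative is offset- and unit-dependent and can label
every frame, while the range reading is invariant to shifting or
rescaling all gas volumes (both properties are tested) and excludes
mid-cycle frames as observed in practice. Extremes are taken over the
whole recording of a ventilatory condition, not per breath. A zero range
raises a degenerate-series error; a band ≥ 0.5 would let the two phases
overlap and is rejected.

## Distributions

Density histograms use 150 left-closed bins of 10 HU from −1000 to
+500 HU (the final bin closed at +500); fraction histograms use 100 bins
of 1 %. Weights are normalized to sum to one so volumes with different
voxel counts compare directly. Voxels outside the HU range (dense
contrast, metal) are excluded from normalization and reported as a
count — clamping them would distort the extreme bins. Pearson's r is
computed over all bins, shared zeros included, as the fixed-bin design
implies. A mean-of-histograms helper averages after per-volume
normalization, keeping each volume's weight equal.

## Agreement statistics

Differences are dynamic-slice minus whole-lung throughout. For n paired
differences with mean d̄ and standard deviation s: LoA = d̄ ± 1.96 s; the
CI of d̄ uses the t quantile with n−1 degrees of freedom and standard
error s/√n; each LoA's CI uses the classical large-sample standard error
s·√(3/n) with the same t quantile. The paired t test is two-sided and no
multiple-testing correction is applied (per-variable p values are
reported). Statistics on fractions are computed on the percentage scale.
The phase-bias split reports mean (SD) of the bias within each phase and
the inspiratory-minus-expiratory difference as mean ± 1.96 SD of the
paired differences. Slice-position regression pools observations
expressed relative to the most caudal slice and fits ordinary least
squares against cranial offset in mm. Correlation of a constant series
is undefined and reported as NaN rather than an error, since an
eight-variable report should not fail because one compartment is empty.

## Displacement analysis

Registration is consumed, not performed: input is a dense displacement
field in mm, expiration → inspiration, with positive cranio-caudal
component meaning caudal movement. Regional means divide the slice lung
mask's bounding extent along the anterior→posterior axis into 12 bands
of equal height (empty bands near the lung border are reported as
missing, not dropped); this uses the mask extent rather than the full
image extent so the regions track the lung. Movement fractions bin
caudal displacement at 5 / 10 / 15 mm — one, two and three slice
thicknesses; cranial (negative) movement counts in the first bin and
anything beyond 15 mm is reported separately. Group summaries use
medians and IQRs with linear interpolation between order statistics.

## The synthetic phantom

The phantom emulates the features of a supine, ventilated, contrast-
enhanced thorax that the pipeline must handle: two elliptical lung
fields inside a body ellipse; a linear anterior→posterior gas-fraction
gradient (defaults 0.85 → 0.25) with the posterior lung dependent; a
dependent atelectatic band (default 12 % of the lung depth at gas
fraction 0.03); cranio-caudal vessel cylinders carrying 90 % iodinated
blood over ~3 % of the lung cross-section, which make the density
distribution bimodal; background perfusion proportional to tissue
density; and aorta/muscle ROIs outside the lungs for calibration.
Fractions sum to one exactly by construction. Rendering applies the
linear mixing model per energy plus independent additive Gaussian HU
noise (default 5 HU per energy — the magnitude is a configurable
assumption, not a scanner calibration). No X-ray physics (beam
hardening, scatter, reconstruction kernels) is modelled, so passing
tests demonstrate correctness of the analysis chain, not robustness to
spectral artefacts of real scanners.

Tidal dynamics sample a raised-cosine gas-volume waveform at 1 Hz
between the end-expiratory volume and end-expiratory + amplitude
(default 30 % of end-expiratory), reaching both extremes exactly. The
tidal gas increment is distributed across voxels in proportion to their
available headroom (1 − blood − end-expiratory gas), so per-frame
fractions stay on the simplex with soft tissue absorbing the
complement; an amplitude exceeding the slab's total headroom is
rejected. Ground-truth phase labels come from an independent, loop-based
application of the band rule to the noiseless waveform.

The displacement field is defined on a coarse control grid (3-mm
spacing, matching common free-form-deformation practice) and linearly
interpolated to the voxel grid; a constant control field is reproduced
exactly. The cranio-caudal profile is a sin² bump over the lung's
anterior→posterior extent scaled to the peak caudal displacement
(default 12 mm), concentrating movement mid-gravitationally; in-plane
components are zero. The generator stores per-region mean displacements
computed by direct per-voxel averaging as an oracle for the analysis
module.

Default problem sizes are deliberately miniature — a 96×128×12 grid at
0.5×0.5×5 mm (48×64 mm in-plane), with 48×64×6 used in tests and
experiments — chosen so full end-to-end experiments over dozens of
conditions run in seconds; all geometry scales with the spec.

## Synthetic experiments

The null agreement experiment generates one phantom per condition,
renders it with noise, calibrates, decomposes, and compares the whole
lung against a pseudo dynamic slice drawn by sampling (with replacement)
as many voxels as the central slab holds from the whole-lung voxel
population. The slice's composition then equals the whole lung's in
expectation, so all eight mean differences are zero up to sampling
noise — a calibration check of the entire chain. The Bland–Altman
recovery experiment draws 96 paired conditions with Gaussian differences
(mean −30, SD 16). A single study checks the mean difference to within
3σ/√n; the limits of agreement are checked as the mean over 200
replicated studies against the true μ ± 1.96σ, because one study's LoA
estimate has standard error σ√(3/n) ≈ 2.8 at n = 96 — far wider than the
2 % calibration band the replicated mean is held to.

## Known limitations

* The linear mixing forward model ignores spectral effects; real DECT
  coefficients drift with patient size and tube settings.
* The phantom's geometry is cylindrical along the cranio-caudal axis and
  its gradient strictly monotone; real lungs have lobar structure,
  hilar vessels and bronchi that the movement analysis here does not
  emulate.
* The frame rule assumes one recording per ventilatory condition; no
  breath segmentation or interpolation between frames is attempted.
* Bland–Altman confidence intervals use the classical large-sample LoA
  standard error; exact small-sample intervals are not implemented.
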