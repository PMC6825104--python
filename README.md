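# dectlung

Dual-energy CT (DECT) analysis of lung aeration, with everything needed to
validate a dynamic single-slice protocol against whole-lung imaging on a
synthetic thorax with known ground truth.

## The problem

Dynamic single-slice CT (dCT) images one thin slab of the thorax at ~1 Hz
while the lung moves with ventilation. It is the standard way to study
intra-tidal aeration changes — cyclical atelectasis, recruitment — in
experimental lung injury, but it raises two validity questions: does one
slice represent the whole lung, and does the slice's inspiratory movement
out of the scanner field-of-view bias the comparison between inspiration
and expiration? Answering these requires the full processing chain from
raw dual-energy volumes to agreement statistics. `dectlung` implements
that chain for Python users:

1. **Three-material differentiation.** A voxel imaged at two tube
   energies yields two CT densities. Modelling it as a mixture of gas,
   soft tissue and iodinated blood whose volume fractions sum to one
   gives a per-voxel linear system

   ```
   HU_low  = f_gas C[gas,low]  + f_tis C[tis,low]  + f_bld C[bld,low]
   HU_high = f_gas C[gas,high] + f_tis C[tis,high] + f_bld C[bld,high]
   1       = f_gas + f_tis + f_bld
   ```

   with coefficients `C` calibrated from ROI means (descending aorta for
   iodinated blood, parasternal muscle for soft tissue, −1000 HU at both
   energies for gas). Out-of-simplex solutions are clipped to zero and
   renormalized, with the projection distance kept as a diagnostic. A
   70 %:30 % merge of the two energy volumes supports segmentation and
   density histograms.
2. **Aeration compartments** from the gas volume fraction at cut-offs
   10 / 50 / 90 % (≡ −100 / −500 / −900 HU on non-contrast scans):
   atelectasis, poor, normal aeration, overdistension.
3. **Dynamic frame classification.** Per-frame gas volume = slab volume ×
   mean gas fraction; frames within 30 % of the min-to-max range from the
   minimum are expiratory, from the maximum inspiratory, the rest
   excluded.
4. **Distributions** — normalized histograms (10-HU bins from −1000 to
   +500 HU; 1 % fraction bins) compared with Pearson's r.
5. **Agreement statistics** — for eight variables of interest (mean
   merged CT density and volume fractions of soft tissue, gas, iodinated
   blood, and the four aeration compartments): linear correlation r²,
   Bland–Altman mean difference and 95 % limits of agreement with
   confidence intervals, paired t tests, inspiratory/expiratory bias
   split, and per-mm regression across adjacent slices.
6. **Displacement analysis** — regional means of the cranio-caudal
   component of an expiration→inspiration displacement field over 12
   equal-height gravitational regions, plus the fraction of the slice
   moving less than one (< 5 mm), one-to-two (5–10 mm) or more than two
   (10–15 mm) slice thicknesses.
7. **Synthetic phantom** — a supine thorax with a gravitational aeration
   gradient, dependent atelectasis, cranio-caudal vessels, calibration
   anatomy, tidal gas modulation and a smooth displacement field, all
   with exact ground truth, so every stage above is testable end to end.

## Worked example

```bash
python examples/01_decompose_phantom.py
```

```
calibrated basis (HU at low/high energy):
  gas               -1000.0  -1000.0
  soft_tissue          59.7     54.8
  iodinated_blood     400.8    250.5
mean gas              recovered  50.4 %   true  50.7 %
mean soft tissue      recovered  42.3 %   true  42.6 %
mean iodinated blood  recovered   7.3 %   true   6.7 %
```

The basis calibrated from noisy ROIs sits within a HU of the true
material coefficients, and the decomposed lung-mean volume fractions
recover the phantom's ground truth to well under one percentage point at
5-HU image noise. The other examples cover each capability:
`02_aeration_compartments.py` (compartment fractions partitioning the
lung), `03_tidal_frames.py` (frame table with gas volume and phase
label), `04_distributions.py` (histogram conservation and slab-vs-lung
correlation), `05_agreement.py` (Table-2-style agreement report under a
null construction), `06_displacement.py` (12-region displacement profile
peaking mid-gravitationally and movement-fraction bins).

A thin CLI mirrors the library for shell use — subcommands `simulate`,
`decompose`, `segment`, `frames`, `histogram`, `agree`, `displace` and
`run` (full pipeline with a reproducibility manifest):

```bash
dectlung run --out out/ --seed 1
```

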