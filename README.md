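# octaquant

Quantification of corneal neovascularisation from angiography images,
with inter-modality agreement analysis and a seeded synthetic
angiography simulator.

Corneal vascularisation — pathological vessel ingrowth into the
normally avascular cornea — is monitored with 2D dye angiography
(indocyanine green angiography, ICGA) and, increasingly, with
non-invasive optical coherence tomography angiography (OCTA).
Different OCTA algorithms produce images with different noise and
artefact character: amplitude-decorrelation systems (SSADA) are smooth
but replicate superficial vessel signal into deeper layers (projection
artefacts), while complex-signal systems (OMAG) avoid projection
artefacts but carry more motion-line noise.  `octaquant` implements the
standard analysis used to compare such systems, for researchers
validating OCTA against dye angiography:

- **Vessel density** — an en-face angiogram is registered to its
  matched counterparts, filtered for speckle and full-width motion
  lines, binarized with Otsu's automatic threshold, and the density is
  the foreground fraction: `VD = 100 · white pixels / total pixels`.
- **Depth-slab analysis** — an OCTA volume is partitioned into
  contiguous 50 μm en-face slabs `[kT, (k+1)T)` (maximum-intensity
  projection), each quantified independently.
- **Agreement statistics** — per-modality mean ± SD (sample SD,
  `n−1`), paired t-tests, Pearson *r*, Bland–Altman 95 % limits of
  agreement `d̄ ± 1.96·s_d` with confidence intervals
  (SE `= s_d·√(3/n)`, t quantile at `n−1` df), and unweighted Cohen's
  κ for ordinal 0–4 image-quality scores.
- **Synthetic angiography** — seeded vessel trees grown from the
  limbus by a biased random walk, rendered per modality profile (PSF
  width, multiplicative speckle, motion-line rate, projection
  strength) with exact ground-truth masks, so the whole chain can be
  validated against known truth.

The package ships `table1.csv`, a 32-measurement three-modality
reference dataset (16 subjects × 2 weekly time points, vessel density
per ICGA / OMAG / SSADA) used throughout the tests and the worked
example below.

## Worked example

Inter-modality agreement on the bundled reference dataset:

```sh
octaquant compare --out report/
```

prints

```
Per-modality vessel density (%):
  ICGA   n= 32   16.52 +/- 8.94
  OMAG   n= 32   16.23 +/- 9.51
  SSADA  n= 32   17.09 +/- 7.34

Pairwise agreement (difference = first - second):
  ICGA vs OMAG: mean diff 0.29, LOA (-5.79, 6.37), r=0.95, t(31)=0.54, p=0.596
  ICGA vs SSADA: mean diff -0.57, LOA (-6.84, 5.69), r=0.94, t(31)=-1.01, p=0.318
  SSADA vs OMAG: mean diff 0.87, LOA (-7.43, 9.17), r=0.91, t(31)=1.16, p=0.256
```

All three modality pairs correlate strongly (r > 0.9) and none differ
significantly in mean density (p > 0.05): the two OCTA systems and the
dye reference measure essentially the same vessel density, with ICGA
closest to OMAG (smallest mean difference and narrowest limits of
agreement).  The same analysis is available in the library as
`octaquant.agreement_report(octaquant.load_table1_fixture())`.

A fully synthetic end-to-end experiment (simulate → register →
quantify → compare), reproducible from one seed:

```sh
octaquant run --subjects 4 --seed 7 --out run/
octaquant simulate --modality SSADA --seed 5 --out sim/
octaquant slabs sim/SSADA_volume.tif --axial-spacing-um 50 --out slabs.csv
```

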