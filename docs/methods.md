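# Methods

## The measurement model

Vessel density is defined on a binarized en-face angiogram as the
percentage of foreground pixels.  The quantification chain is:

1. **Registration** (matched multi-modality sets only): each moving
   image is aligned to a designated fixed image by the integer
   translation maximizing normalized cross-correlation over the
   overlap, computed exhaustively with FFT-accumulated sums.  Ties
   break to the smallest translation magnitude, then lexicographically
   by (dy, dx); shifts leaving less than 25 % of the fixed frame in
   overlap are rejected.  Translation-only rigid registration is
   sufficient because matched acquisitions image the same region of
   interest at the same scale; rotation and sub-pixel refinement are
   deliberately out of scope.
2. **Motion-line suppression**: a motion artefact is a full-width line
   elevated at *every* position along it, so the detector uses each
   line's 25th-percentile intensity.  A line is flagged when that
   statistic deviates from the median of its four surrounding lines
   (its *prominence*) by more than `line_mad_factor` (default 5) times
   the MAD of all prominences, floored at 0.05 intensity units so that
   exactly-equal quantized backgrounds cannot make every line an
   outlier.  Flagged lines are replaced by the average of their nearest
   unflagged neighbours.  The lower-quartile statistic is what makes
   the detector blind to anatomy: a row crossing vessels — even many —
   still has background in its lower quartile, while a genuine
   full-width artefact does not.
3. **Speckle filtering**: a median filter over a diamond (city-block)
   neighbourhood of radius 1 (the 4-neighbour cross).  The diamond
   footprint matters: a full 3×3 square median bridges diagonal
   sub-resolution gaps between adjacent branches and inflates measured
   density by up to ~2 percentage points in dense networks, while the
   cross removes isolated speckle without bridging.
4. **Otsu threshold**: the level in 0..255 maximizing the between-class
   variance ω₀ω₁(μ₀−μ₁)² of the histogram partition {≤t}/{>t}; ties
   break to the lowest qualifying level.  RGB input collapses to
   grayscale by the unweighted channel mean before thresholding.
5. **Binarization and density**: foreground is `intensity > t`;
   density is 100 × foreground / total pixels, restricted to the
   common-overlap ROI when registration ran.

Degenerate inputs: a constant image thresholds nowhere and is reported
as 0 % density with a `degenerate` flag (no contrast = no evidence of
vessels).  The same flag is raised when the two Otsu classes' mean
separation falls below `min_contrast` (default 0.06 on the unit
intensity scale): below that floor the threshold is splitting
background noise, which would otherwise report a vessel-free noisy
slab as ~40–50 % "density".  Otsu's method is known to be unreliable
when the true foreground fraction approaches zero; the contrast guard
is the package's explicit handling of that regime.

## Depth-slab analysis

Volumes are partitioned into contiguous half-open depth windows
`[kT, (k+1)T)` μm (default T = 50) measured from the anterior surface.
Slice k, with depth centre (k + 0.5)·spacing, joins the window
containing its centre.  Each slab is collapsed by maximum-intensity
projection (the dominant en-face convention; mean and sum are
selectable) and quantified like any 2D image.  A final partial slab is
kept and flagged rather than dropped.

## The synthetic angiography simulator

The simulator provides ground truth the real study cannot: exact vessel
masks.  Vasculature grows from `n_sprouts` points on the image border
(the limbus) toward the cornea centre by a biased random walk —
per step, each active tip advances `step_len` along a direction
blending its noise-perturbed heading with the centre pull
(`center_bias`, default 0.35), and branches with probability
`branch_prob` (child radius × `taper`).  Depth starts uniform in
`depth_range_um` (default 100–350 μm, mid-stromal) and drifts by a
per-step Gaussian.  Geometry and branching consume two independent
streams spawned from the seed, so the branching process is a pure
Bernoulli sequence that tests can replay.

Rendering rasterizes segments as tubes of their radius (pixel-centre
inclusion), blurs with a Gaussian PSF of the modality's stated lateral
resolution, adds background, applies unit-mean multiplicative gamma
speckle, and overwrites a Poisson number of full-width lines at a
bright motion level.  Output is clipped to [0,1] and quantized to
8 bit, so synthetic data round-trips the same file formats as real
exports.

Default modality profiles (all overridable):

| parameter | SSADA | OMAG | ICGA |
|---|---|---|---|
| PSF FWHM (μm) | 15 | 20 | 25 |
| speckle shape (gamma) | 18 | 9 | 40 |
| motion lines / image | 0.6 | 2.0 | 0 |
| projection strength | 0.55 | 0 | — |
| background level | 0.10 | 0.12 | 0.08 |
| volumes | yes | yes | no |

PSF widths follow the two OCTA systems' printed lateral resolutions;
the remaining magnitudes are qualitative rankings (SSADA smoother with
projection artefacts, OMAG noisier with more motion lines, ICGA a
smooth 2D reference), since no quantitative noise figures exist for
these devices — they are tuning knobs, not claims.  In volumes, each
vessel voxel's signal is replicated into all deeper voxels at the same
lateral position scaled by `projection_strength · exp(−Δz/decay)` with
a 250 μm decay length, chosen so projected tails remain detectable
several slabs below the vasculature, mimicking the depth-persistent
tail artefact of amplitude-decorrelation OCTA.

What the simulator does **not** emulate: OCT speckle correlation
structure (speckle here is pixel-independent), depth-dependent signal
attenuation, layer-segmentation errors, non-parallel slab surfaces,
vessel pulsation/flow contrast, and realistic corneal anatomy beyond an
optional disc mask.  Passing recovery tests therefore demonstrates that
the measurement chain is unbiased and monotone on images with the
stated noise character — not that any specific device is accurately
modelled.

## Agreement statistics

All summaries use the sample SD (n−1).  The paired t-test is
`t = d̄/(s_d/√n)` with df = n−1 and a two-sided p.  Bland–Altman limits
of agreement are `d̄ ± 1.96·s_d` (fixed 1.96 multiplier, per the
standard definition); each limit's 95 % CI uses the large-sample
standard error `s_d·√(3/n)` with a t(n−1) quantile.  Cohen's κ is
unweighted over the 5×5 contingency table of 0–4 quality scores, with
the degenerate `p_e = 1` case defined as κ = 1 when observed agreement
is also perfect.  Tests are two-sided at α = 0.05 with no
multiple-testing correction.  Rendered tables round to 2 decimals; CSV
exports keep full precision.

The bundled reference dataset reproduces its published per-modality
means and SDs exactly at two decimals, and its pairwise comparisons
satisfy r > 0.9 and p > 0.05 throughout.  The individually published
pairwise p-values and limits of agreement for this dataset are *not*
recoverable from the printed values under any standard convention
(paired/unpaired, n or n−1, pooled or per-week); this package reports
the recomputed values rather than matching the published ones.  The
serial-to-week mapping of the fixture (serials 1–16 → week 2, 17–32 →
week 1) is an assumption inferred from the magnitude pattern, recorded
in the loader's documentation.

## Problem sizes and numerical choices

Validation experiments use 160×160 images at 12 μm/pixel (a ~2 mm
field), 10-slice volumes at 50 μm axial spacing, 50-tree density
sweeps spanning ~2–40 % true density, and 5 injected shifts for
registration — sizes at which every suite runs in seconds while leaving
the statistics stable.  Determinism: every stochastic operation is a
pure function of its inputs and an integer seed; end-to-end runs derive
per-subject seeds via `SeedSequence(master, spawn_key=(subject, week,
stream))`, so adding subjects never perturbs existing ones.

Known limitations: registration is translation-only; the motion-line
detector assumes single-line artefacts (two adjacent artefact lines
shadow each other's reference); Otsu densities below ~1 % true density
are unreliable even with the contrast guard; and the simulator's noise
magnitudes are plausible rather than device-calibrated.
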