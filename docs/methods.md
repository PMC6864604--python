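# Methods

## Readout model

A developed LFA strip photographed on a white background has near-neutral
background pixels (red ≈ green) and two colloidal-gold lines whose pigment
absorbs green more strongly than red. The readout therefore works entirely in
the red/green ratio plane `r(x,y) = I_R(x,y) / I_G(x,y)`: background sits at
r ≈ 1, line pixels well above. Pixels with `I_G = 0` have no defined ratio;
they are flagged invalid and excluded from histograms and masks rather than
clamped, so they can never inject infinite ratios into the threshold search.

Segmentation thresholds `r` with Otsu's criterion computed **on the
control-line region only**: the control line is fully developed on any valid
strip, so its region always contains the two populations (background, line)
the threshold must separate — the test-line region may contain only
background. The resulting `TH_mask` is then applied to both line regions
(optionally the whole frame). The mask uses a strict inequality,
`r > TH_mask`.

The signal of a region is the sum of red intensities over its masked pixels;
the feature is `T/C = S_test / S_control`. Multiplying every channel by a
lighting factor k scales both sums by k and cancels in the ratio, which is
what makes the feature usable across uncontrolled ambient lighting.
`S_control = 0` is not a measurement but an invalid assay (no control line)
and raises an error.

## Otsu implementation

The threshold search is authored here rather than delegated, because the
pipeline fixes a specific convention for real-valued ratios: a histogram of
256 uniform bins spanning the observed value range of the thresholding
region, candidate thresholds at interior bin edges, total intra-class
variance computed from bin centers, and ties resolved toward the smallest
threshold (so a two-valued region thresholds just above its lower cluster).
The multilevel generalisation enumerates cut combinations and returns
ascending thresholds; the pipeline default is `levels = 2` — the mask uses
exactly one threshold — with the level count left as a configuration knob.
Tests cross-check the search against a brute-force minimizer that uses raw
values instead of bin centers, and against scikit-image's Otsu on clustered
data.

## ROI geometry

The center cell of the 3×3 framing grid is the middle ninth of the image by
floor division (`x ∈ [⌊w/3⌋, ⌊2w/3⌋)`, likewise for y). The cell is divided
into three equal horizontal bands on a 0..3 inner lattice, again by floor
splits with remainder rows assigned to the last band, so the three bands tile
the cell exactly. The test line is the middle band; the control line the
upper band by default, with a `flipped` flag for strips framed with the flow
direction reversed. The lower band is unused background. Automatic strip
detection is out of scope: the capture protocol aligns the strip to the grid,
and the geometry assumes it.

## Synthetic strips

The generator renders the forward model the readout assumes: uniform bright
background (200, 200, 200), line color (160, 130, 130) — red/green ratio
1.23 versus 1.0, the intensity regime of real strips — control line in the
upper band, test line in the middle band, both as centered rectangles of
configurable thickness (default 0.2 of the center-cell height; a thickness
that does not fit inside its band is a geometry error).

**Line strength is modeled as developed coverage, not color blending**: a
strength-s line paints the fraction s of its band rectangle (a centered
sub-rectangle) at full line color. This is a deliberate design choice. With
per-pixel color blending, any pixel whose ratio crosses the threshold
contributes its full red intensity to the sum, so S_test would jump to
count × red as soon as a faint line crosses TH_mask and then *decrease* with
further development (line red 160 < background red 200) — the opposite of the
observed dose-response. Coverage painting makes T/C equal the painted-area
ratio: zero for an absent line, strictly increasing in strength with ~0.01
resolution (one column of the 100-px band), spanning the full [0, 1] range of
real T/C tables. Because both lines share one painted color, the illumination
factor cancels *exactly* in T/C even after 8-bit quantization — dimming to
k = 0.5 changes T/C by 0.0 percent, comfortably inside the ≤ 0.5 % drift
budget the feature is designed for. For k > 1 channel clipping at 255 can
break this cancellation; the generator permits it but the invariance property
is only claimed for k ≤ 1.

Noise is additive, Gaussian, independent per pixel and channel (default
σ = 2 intensity levels, a light sensor-noise regime; 0 gives exact geometry),
applied after illumination scaling and followed by rounding and clipping.
Identical specs and seeds give byte-identical images. The generator does not
attempt photorealism: no perspective, motion blur, vignetting, wicking
gradients or membrane texture. Passing tests therefore demonstrate the
correctness and invariances of the *algorithm*, not robustness to real-world
capture artifacts.

`strength_for_quantity` inverts the calibration line through a lookup of the
actual pipeline response: the noiseless T/C is measured on a 101-point
strength grid for the default geometry (cached per geometry) and
interpolated, so the chosen strength reproduces the calibrated T/C at a given
quantity to within the grid resolution. Targets outside the achievable
response range raise a range error.

## Calibration

The x-axis is `log10(quantity / 10 fg)`, mapping the standard classes to
x = 0..4; the reference quantity is configurable. The fit is ordinary least
squares with intercept. Figures of merit:

- σ = √(Σ(Y − Y′)²/N) — RMS prediction error with divisor **N**, not N−2:
  it is used as a detection-error scale, not an unbiased variance estimate.
- R² = 1 − SS_res/SS_tot, the conventional coefficient of determination.
- LOD = LOB + 1.645·σ/m and LOQ = 10·σ/m, on the log-quantity axis. LOB
  defaults to 0 when no blank readings exist; with blanks,
  LOB = mean + 1.645·std of the blanks.
- Per-class CV = 100·s/μ with the sample (n−1) standard deviation; a class
  with μ = 0 (all-blank readings) has CV undefined, reported as null rather
  than 0.

Quantity prediction inverts the line, `quantity = 10 fg · 10^((T/C − b)/m)`;
extrapolation beyond the calibrated classes is permitted and should be
flagged by callers. Unit helpers convert mass ↔ concentration
(1 pg/mL × 1 µL = 1 fg; default sample volume 10 µL) and concentration →
molarity given a molecular weight.

The packaged 75-reading table stores the published values verbatim at their
printed 3-decimal precision. Refitting from that precision gives slope
≈ 0.2002, intercept ≈ 0.0146, R² ≈ 0.978 — close to, but not exactly, the
originally reported line (0.203 / 0.0118 / 0.9838, evidently fitted on
unrounded data); tests and the acceptance script assert the consistency bands,
not exact reproduction. Weighted and nonlinear (4PL/5PL) calibration are out
of scope.

## Classification

The classifier feature is the calibrated quantity x̂ = (T/C − b)/m. Since the
map is affine and monotone, classification is equivalent to thresholding T/C
directly; using x̂ keeps the classifier's input on the axis the assay is
linear in. The SVM is a soft-margin linear machine in scikit-learn's native
one-vs-one scheme, C = 1 by default; predictions are majority votes with
vote ties broken by the larger aggregate decision margin and then by class
order. On scalar separable data with large C each pairwise boundary converges
to the midpoint of the closest opposing pair, which the tests verify against
that closed form. Cross-validation is stratified k-fold (default k = 5) with
seeded shuffling; out-of-fold predictions pool into a single confusion matrix
whose overall accuracy is 100 × trace / total. Confusion matrices order
classes by descending quantity, the convention assay tables are printed in.

The published test-set accuracy (98 %) rests on 10 replicate readings per
test strip that were never printed; it cannot be recomputed from available
data. What can be derived is its error mode: a large-C model trained on the
two training sets puts the 10 pg/100 pg boundary at T/C ≈ 0.716, so the
held-out 10 pg reading at 0.722 crosses into the 100 pg class — the single
error the published matrix shows. The acceptance script reports the honest
accuracy over the five printed held-out readings per class (84 % under the
large-C model, which also exposes two 1 pg readings and one 100 pg reading
sitting across their midpoint boundaries) rather than asserting a number the
data cannot support.

## Problem sizes and numerical notes

Synthetic strips default to 300×300 px (center cell 100×100, line bands
100×20), large enough that T/C has ~1 % coverage resolution while the whole
suite and acceptance script run in seconds. End-to-end checks use 25 strips
(5 classes × 5 replicas), mirroring the reference design of 5 readings per
strip; the response-curve lookup uses 101 strengths. The Otsu search is
deterministic; all stochastic steps (noise, fold shuffling) flow from
explicit seeds. Degenerate inputs fail loudly and specifically: constant
ratio regions (blank strips) raise a degenerate-input error, absent control
lines an invalid-strip error, rank-deficient calibration designs a
degenerate-input error, and single-class training sets a value error.
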