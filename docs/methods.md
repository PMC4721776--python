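# Methods

This note documents the models, the parameters that matter, the numerical
choices made where the procedure left room, and what the synthetic data
can and cannot show.

## Segmentation

The hand is assumed brighter than the background in both modalities
(scanner: illuminated skin on a dark lid; IR: warm skin on a cool
background), so the gray histogram is bimodal. The threshold is the
histogram valley between the two dominant peaks (mode method). Raw
histograms, especially from IR sensors, are spiky, so counts are smoothed
with a 5-bin moving average before extremum detection; the two local
maxima with the largest smoothed counts are the peaks, and the valley is
the minimum-count bin strictly between them, ties broken at the median
index of the minimal run (deterministic and symmetric). Fewer than two
maxima raises a "no bimodal structure" error rather than guessing.

Binarization keeps pixels ≥ threshold. The mask is repaired by two
dilations followed by two erosions with a 3×3 square structuring element —
the smallest symmetric choice — which closes the dark principal-line
pixels that fall below threshold and smooths boundary nicks. Erosion
treats out-of-grid cells as foreground: this is the exact set-theoretic
dual of dilation (which treats them as background) and preserves the
wrist's contact with the bottom image edge through the repair. One rule is
an addition of this implementation: only the largest 8-connected component
is kept, which removes fingernail blobs and isolated bright noise. A side
effect of the closing is that a digitized silhouette is not reproduced
bit-exactly: a small fraction (~0.1%) of concave boundary pixels is filled
in, never removed.

## ROI localization

Input orientation is a documented requirement: fingers up, wrist touching
the bottom image edge. The inner border is traced with a Moore-neighbour
walk starting at the leftmost foreground pixel of the bottom-most
foreground row, proceeding counterclockwise (as displayed) with Jacob's
stopping criterion. The wrist midpoint W_M is the midpoint of the largest
foreground run on the bottom row; the distance profile D_E(i) is the
Euclidean distance from W_M to each contour pixel.

Fingertips are the profile's local maxima, finger webs the minima between
consecutive tips. The profile is smoothed over 2% of the contour length
(circular padding) and tip peaks must have prominence ≥ 5% of the profile
range; anything other than exactly five tips raises "hand not
outstretched" — this extrema gate stands in for a curvature-based
outstretched-hand check whose details are not specified anywhere. Webs are
indexed FW1 (thumb–index) through FW4 (ring–little); the trace runs up the
thumb side first, so contour order is identity order.

The rotation θ = arctan(Δrow/Δcol) of the FW2–FW4 segment, reported in
(−90°, 90°], is removed by rotating the image by −θ about the FW2/FW4
midpoint (bilinear warp); web coordinates are transformed analytically
rather than re-detected (cheaper and exact). The ROI square has side
1.5·|FW2FW4|, top edge parallel to the web line at offset |FW2FW4|/4
toward the palm (increasing row), horizontally centered on the web
midpoint. The crop is sampled subpixel (bilinear) at its native size, then
resized to 256×256 (palm) or 64×64 (dorsum) — cropping then resizing was
chosen over direct sampling at the target size; the difference is below
the interpolation noise floor. A quad leaving the frame raises "ROI out of
frame" instead of padding silently.

## Wavelet fusion

The palm ROI is gray-inverted (255−g) so its dark lines become bright like
the IR veins. Both ROIs are decomposed with the orthonormal Haar filter
pair (taps 1/√2), palm three levels, vein one level, meeting at 32×32
subbands. Periodization boundary handling is used; for Haar on even sides
it coincides with any other extension and guarantees perfect
reconstruction to machine precision.

The Avg-Max rule averages the LL subbands and takes the elementwise
*signed* maximum of the detail subbands, exactly as the rule is stated;
magnitude-max is the more common variant in the fusion literature and
would differ only where both coefficients are negative. Coefficients are
fused raw, with no rescaling between modalities (exposed as
`prefuse_normalize`, default off). A consequence worth knowing: under
orthonormal Haar, an LL coefficient at depth d carries gain 2^d, so the
averaged approximation weights palm luminance (depth 3, gain 8) four times
the vein's (depth 1, gain 2). Two constant inputs c1' (inverted palm) and
c2 therefore fuse to c1'/2 + c2/8, not their plain mean. This weighting is
a property of the different-resolution scheme itself; equalizing it would
break the exact identity that fusing a set with itself reproduces the
inverted palm through the three IDWT stages, which is the stronger
structural guarantee and is enforced in the tests.

Reconstruction runs three IDWT stages: fused set → 64×64, then with the
palm's level-2 details → 128×128, then level-1 details → 256×256. Palm
detail subbands at levels 1–2 pass through unfused (the vein image has no
counterpart at those scales). Output is rounded half-up and clipped to
[0, 255]. Alternative rules (avg, max, min, weighted with configurable
weight) are available for comparison runs.

## Line features

Four 3×3 Sobel kernels (0°, 45°, 90°, 135°) are convolved with replicate
padding; each pixel keeps the maximum response *magnitude*. Magnitude was
chosen over signed maximum because a gray level is non-negative and
because it makes the operator bank exactly closed under 90° image
rotation, a symmetry the signed variant loses (rot90 maps two kernels to
their negatives). The max-of-four image is min-max rescaled to 0–255 per
image, since the downstream threshold is relative, not absolute.

Binarization uses iterative threshold selection: a seeded random integer
threshold strictly between the image extremes, then Th ← round((μ_B +
μ_O)/2) with background = pixels ≤ Th until the threshold repeats. On
two-level images the fixed point is unique and reached from every start
(e.g. 105 for levels 10/200); on natural images multiple fixed points can
exist, which is why the seed is a recorded parameter. Pixels strictly
above the final threshold form the line-like image (LLI). A constant image
raises "no separation".

The feature-pass filter counts LLI pixels in non-overlapping blocks, local
coordinates within each block, row-major. Counts conserve total mass and
refine exactly (a 2b-block count is the sum of its four b-block children).
Block defaults follow the best operating points of the study the pipeline
reproduces: 32 px for 256×256 images, 16 px for 64×64. Before the SVM,
counts are divided by block_px² into [0, 1] — RBF kernels need bounded
feature scales.

## Verification

One two-class soft-margin SVM per enrolled identity (the genuine/impostor
framing makes the one-vs-rest topology natural), RBF kernel
K(x,y) = exp(−‖x−y‖²/2σ²). Unless fixed by the caller, C is selected from
{2⁻², 2⁰, …, 2⁸} and σ from {2⁻⁴, 2⁻², …, 2⁴} × the median pairwise
training distance, by 3-fold cross-validation on the training folds. A
verifier that cannot separate its own training data sets `separable_ =
False` and warns instead of failing.

The k-fold protocol: per identity, (k−1)/k of its captures train as
positives against an equal number of negatives drawn seeded and
round-robin across the other identities (no single impostor dominates,
no replacement); the held-out 1/k are genuine trials (NPT) matched
one-for-one by held-out impostor trials (NNT). FRR = NFR/NPT·100%,
FAR = NFA/NNT·100%, aggregated as counts over identities and folds — the
alternative of averaging per-identity rates would weight identities with
odd fold sizes differently. Reports retain every per-trial decision so the
rates can be recomputed and audited.

## Synthetic data

The generator emulates the acquisition setup the pipeline was designed
for: 845×829 scanner-style palm images and 240×320 IR-style dorsum images,
background gray ≈ 20, skin ≈ 180. The silhouette is a parametric palm
(trapezoid with an elliptic bottom cap and a wrist tongue that always
crosses the bottom edge, even under rotation) plus five capsule fingers
fanned at −10°…+10° so each finger web is a narrow notch — this keeps the
web's location well-defined to a few pixels, and keeps the distance
profile's five-maxima/four-minima structure sharp. On the dorsum canvas
the fingers are thinned (factor 0.72) so the notches stay wider than what
two 3×3 dilations can seal. Principal lines are hard-edged dark (gray 60)
4-px strokes along per-identity Bézier polylines; veins are bright ridges
with Gaussian cross-profile (amplitude 45, σ ≈ 3 px) along a three-branch
tree placed inside the ROI catchment. Capture jitter (rotation ≤ ±15°,
translation ≤ ±20 px, brightness ≤ ±10, additive noise smoothed with a
0.8-px Gaussian so adjacent-pixel noise jumps stay small, as real optics
would) is applied to the *geometry* before rasterization, so ground-truth
webs, tips and traces are exact. Identities are rejection-sampled to
differ by ≥ 2% RMS in anatomical parameters.

The default cohort draws rotation from ±10°, palm translation from
±20 px, dorsum translation from ±8 px (the small canvas would otherwise
push the ROI out of frame), noise σ 3 (scanner) / 1.5 (IR). These are the
fixed study conditions of the shipped evaluation (20 identities × 10
capture pairs, 5-fold protocol).

What the generator does *not* model: real skin texture and wrinkle
families, sensor noise statistics (thermal NETD, scanner optics), palm
creases crossing fingers, left/right hands, partial occlusion, or
anatomically correct thumb opposition. Passing tests demonstrate that the
pipeline recovers aligned ROIs and separates identities whose line/vein
geometry differs under peg-free jitter — they do not certify error rates
on real populations, where within-identity variation is richer and
between-identity differences subtler.

## Problem sizes and numerics

The shipped evaluation uses 20 identities × 10 capture pairs with 5 folds
(400 verification trials per mode), a size at which the whole study runs
in about two minutes on one CPU while still exercising every stage at the
real image resolutions. Degenerate inputs fail loudly with typed errors
(`NoBimodalStructureError`, `HandNotOutstretchedError`,
`RoiOutOfFrameError`, `NoSeparationError`) rather than producing silent
garbage. Haar analysis/synthesis round-trips to ≤ 1e-9; image outputs
round half-up; all random draws flow from explicit seeds (NumPy
`SeedSequence` spawning) and identical seeds reproduce cohorts, folds,
impostor draws and thresholds bit-for-bit.

## Known limitations

- Web ordering assumes the thumb is on the left of the displayed image
  (right-hand, palm-side convention of the generator); mirrored hands
  would swap FW1↔FW4 and shift the ROI.
- The signed-max detail fusion can prefer a weaker palm edge over a
  stronger negative vein coefficient; magnitude-max is one flag away if
  that matters.
- The iterative threshold's fixed point is not always unique on natural
  images; the seed pins the outcome but different seeds can give slightly
  different LLIs.
- FRR/FAR are aggregate counts; per-identity operating points are visible
  only through the stored trial lists.
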