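# Methods

## Problem and model

Enhancing brain tumours on MRI present a bright core whose rim
intensities fade into normal tissue, so the "growing region" is poorly
captured by any single global threshold. The pipeline treats region
extraction as three successive refinements of evidence:

1. a **per-slice candidate** (the biggest connected component of the
   window-stretched slice),
2. a **cross-slice consensus** (the pixelwise union of per-pattern
   biggest blobs — the resultant biggest blob, whose area is the
   confidence score),
3. a **statistical reclassification** (the confidence-interval remap
   plus multi-level thresholding — the confidence region), with the
   region-scalable-fitting (RSF) level set delineating the boundary.

All slices are assumed co-registered (as in BraTS volumes), so fusion
is a plain 2-D union; there is no inter-slice registration.

## Stages, parameters and defaults

### Intensity adjustment
`clip(αx + β, 0, 1)` with `α = 1/(high_in − low_in)` and
`β = −low_in·α`; defaults `low_in = 0.36`, `high_in = 0.78`, the band
where enhancing-tumour intensities concentrate on normalized T1-type
sequences. The map is monotone, so it never reorders pixels; no gamma
term is applied.

### Blob detection
Threshold default is Otsu (maximum between-class variance) on the
adjusted slice — deterministic and parameter-free, appropriate for the
bimodal tumour/non-tumour histogram the adjustment produces.
Connectivity default 8 (diagonal neighbours merge). Labels are
renumbered in raster-scan order of first encounter so the labelling is
reproducible; ties for the biggest area go to the smallest label.
Weights are a dense rank by area (1 = biggest); only the maximum is
used downstream.

### Pattern fusion
Pattern membership is user-supplied slice ranges (default: one range
covering the whole stack). Ranges must be disjoint; each pattern's
blob is the union of its per-slice biggest blobs, slices that binarize
to nothing are skipped, and a pattern where every slice is blank is an
error. The resultant mask is the union over patterns (not its largest
component — the overlay is meant to show all patterns jointly); the
overlay paints patterns from a fixed palette, later patterns
overwriting earlier on overlap.

### RSF level set
The standard region-scalable-fitting formulation: local fitted means
`f_in = K∗(Hε(−φ)·I)/K∗Hε(−φ)` (analogously `f_out`), kernel-weighted
squared-residual fields `e_in`, `e_out`, smoothed Heaviside
`Hε(t) = ½(1 + (2/π)·arctan(t/ε))`, and the explicit-Euler update

```
φ ← φ + Δt·[ δε(φ)·(λ_in·e_in − λ_out·e_out)
             + ν·δε(φ)·κ(φ) + μ·(∇²φ − κ(φ)) ]
```

with κ the curvature of φ. φ is negative inside; a pixel fitting the
exterior better than the interior receives a positive force and leaves
the interior, which is the energy-descent direction for this sign
convention. Defaults: 13×13 Gaussian kernel, σ = 3 (kernel size is a
method constant; σ is our choice at the same spatial scale),
λ_in = λ_out = 1, μ = 1 (distance regularization, replacing
re-initialization), ν = 0.003·255² (length weight), ε = 1, Δt = 0.1,
300 iterations. Residuals are computed on a ×255 rescaled copy of the
[0,1] image so ν keeps its conventional magnitude. Convolutions use
reflect padding; fitted-mean denominators are floored at 1e-10.
Initialization is ±c₀ (c₀ = 2) across the blob's bounding box; for
speed the evolution runs on a window two kernel radii beyond the box
and is pasted back into full-frame coordinates. The evolution runs on
the adjusted image (the same input blob detection sees). The extracted
contour is the interior-side zero-crossing ring: interior pixels with a
non-negative 4-neighbour (this makes the initial contour exactly the
box ring, and the image border counts as exterior).

### Confidence region
Computed from the *score image* — the maximum-intensity projection of
the adjusted slices, so each pixel carries the brightest evidence any
slice offers. Statistics: population σ of the whole image, means over
the four quadrants (row/col split at ⌊n/2⌋, the extra row/col going
bottom/right), band `A1, A2 = ā ∓ z·σ` with z = 1.96 (95% two-sided
normal). Remap per pixel p in quadrant q: keep p if p ≥ ā_q, boost to
`min(1, p + ā_q)` if `A1_q ≤ p < ā_q`, assign ā_q if `p < A1_q`. A2 is
not used as a remap boundary — above-mean pixels are kept regardless;
A1 is the only defensible cut between "boost" and "assign" because it
is the only other threshold the interval defines. The statistics are
taken over the full frame, not a crop: computing quadrant means on a
tumour-centred crop makes every mean tumour-dominated and floods
normal tissue upward in the remap. Then optional single-level Haar
smoothing (detail coefficients zeroed; on by default), multi-level
Otsu with 3 classes, and the final mask = highest-intensity class ∩
dilation of the resultant blob (disk radius = the kernel radius, 6).
An empty resultant blob short-circuits to an empty mask.

### Metrics
DOI = 2|A∩B|/(|A|+|B|), JI = |A∩B|/|A∪B| (both defined as 1 when both
masks are empty), MSE on [0,1] images, PSNR = 10·log₁₀(peak²/MSE) with
peak 1.0 by default (`peak=255` available for 8-bit comparisons) and an
infinite sentinel at MSE 0. The identity D = 2J/(1+J) holds exactly.
Blob areas are reported in pixels; no physical in-plane resolution is
assumed.

## Synthetic phantom

The phantom emulates the features the method exploits: dark background
(0.05), an elliptical brain of tissue intensity 0.45, a tumour disc of
core intensity 0.85 with a linear rim falling to tissue level over
3 px, radius 12 px, centre (64,64) on 128×128 slices, 10 slices. The
centre drifts 1 px/slice and the drift direction flips after slice 5,
giving two pattern groups whose fused blob is a strict superset of any
single-slice blob — this is what makes the fusion stage meaningful.
Additive Gaussian noise (σ = 0.02 default) is clipped to [0,1]. Truth
is the full disc including the rim. Slice numbering starts at 65 to
mirror the tumour-visible window of a 155-slice volume.

What the phantom does *not* model: anatomy, multi-sequence contrast
(flair/T1/T2/T1CE), Rician noise statistics, bias fields, partial
voluming, or irregular tumour shape. Passing tests therefore
demonstrate the pipeline's mechanics and statistical behaviour, not
clinical performance on real BraTS data — reproducing the published
BraTS-average scores would require the external dataset and is out of
scope.

## Numerical choices

- Otsu variants are histogram-based (256 bins); on continuous images
  the 2-class multi-Otsu cut can differ from single Otsu by one bin,
  flipping a handful of borderline pixels — tests compare masks by
  overlap, not bitwise, in that one cross-check.
- The worked 8×8 example uses dyadic intensities so every quadrant
  mean, σ and remap output is exact in float64 and can be frozen as an
  equality fixture.
- Volumes are written as 16-bit NIfTI (round-trip error ≤ 1/65535),
  masks as 8-bit labels (bit-exact round trip). Integer volumes are
  scaled by their dtype range on load; float volumes outside [0,1] are
  min-max normalized, and a constant volume maps to zeros.
- Problem sizes: the acceptance script uses five 10×128×128 phantoms
  and a single 80×80 disc with 500 RSF iterations — large enough that
  the disc truth area matches πr² within 2% while the whole suite
  completes in well under a minute.

## Known limitations

- Pattern ranges are user input; the published procedure identifies
  them by visual analysis and gives no algorithm. (An automatic
  Dice-similarity grouping is a possible extension but is not enabled.)
- The RSF stage informs the exported contour/delineation but the final
  mask comes from the confidence-interval classification; on phantoms
  the two agree closely.
- Explicit Euler with Δt = 0.1 is stable for the default weights but
  not unconditionally; a divergence error reports the iteration if φ
  turns non-finite.
- 3-D fusion, DICOM ingestion, skull stripping, and morphological
  cleanup are intentionally absent.
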