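# crcd — confidence-region contour detection for brain-tumour MRI

Enhancing brain tumours on MRI have boundary intensities that blend into
normal tissue, so a single threshold under- or over-segments the growing
region. `crcd` implements a region-extraction pipeline that tackles this
with a *confidence score* and a *confidence region*:

1. **Intensity adjustment** — each slice is window-stretched,
   `clip(αx + β, 0, 1)` with `α = 1/(h−l)`, `β = −lα`; the default
   window `[0.36, 0.78]` isolates the enhancing-tumour band.
2. **Biggest blob** — the adjusted slice is Otsu-thresholded, connected
   components are labelled (8-connectivity) and the maximal-area
   component is kept as the per-slice tumour candidate.
3. **Pattern fusion** — consecutive slices with similar tumour structure
   form patterns (e.g. two groups of five slices); per-pattern blobs are
   fused pixelwise into the *resultant biggest blob*. Its pixel count is
   the confidence score; an RGB overlay records pattern provenance.
4. **RSF level set** — a contour seeded at the blob's bounding box is
   evolved under the region-scalable-fitting energy
   `E(φ) = Σ λ₁e₁Hε(−φ) + λ₂e₂Hε(φ) + ν|∇Hε(φ)| + μP(φ)`,
   with 13×13 Gaussian-kernel local fitted means, delineating the
   tumour boundary.
5. **Confidence region** — the score image is remapped per quadrant
   using the 95% band `A1, A2 = ā ∓ 1.96σ` (keep above-mean pixels,
   boost the `[A1, ā)` band by `ā`, assign `ā` below `A1`), Haar-smoothed,
   multi-Otsu classified; the top class ∩ dilated blob is the final mask.
6. **Evaluation** — Dice overlap index (DOI), Jaccard index (JI), MSE
   and PSNR against ground truth.

A seeded synthetic phantom (drifting bright tumour disc with an
intensity-falloff rim on textured tissue) exercises every stage without
external data.

## Worked example

```bash
crcd phantom --seed 1 --out ph/
crcd segment ph/volume.nii.gz --slice-offset 65 \
     --pattern 65:69 --pattern 70:74 --out seg/
crcd evaluate seg/confidence_region.nii.gz ph/truth.nii.gz
```

prints

```
confidence score: 875
confidence-region pixels: 848
outputs written to seg
name,doi,ji,mse,psnr
confidence_region.nii,0.9237,0.8583,0.008545,20.6829
```

The confidence score (875) is the pixel area of the fused resultant
biggest blob across both pattern groups; 848 pixels survive the
confidence-interval classification as the final tumour mask, which
overlaps the fused phantom truth with Dice 0.92 / Jaccard 0.86. The
same computation is available from Python via
`crcd.make_phantom`, `crcd.segment_volume` and
`crcd.evaluate_segmentation`.

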