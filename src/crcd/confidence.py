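"""Confidence-interval transform: confidence score -> confidence region.

The score image (the adjusted intensity image carrying the resultant
biggest blob) is statistically remapped so that tumour-like intensities
separate cleanly before multi-level thresholding:

1. the population standard deviation σ of the whole image is computed;
2. the image is split into four quadrants and a mean ā_q per quadrant;
3. a 95% confidence band [A1, A2] = ā_q ∓ 1.96·σ around each mean;
4. each pixel p in quadrant q is remapped with a three-band rule:
   p ≥ ā_q keeps its value, A1_q ≤ p < ā_q is boosted by ā_q (capped
   at 1), p < A1_q is set to ā_q;
5. an optional single-level Haar wavelet smoothing (detail
   coefficients zeroed);
6. multi-level Otsu thresholding; the final tumour mask is the highest
   intensity class intersected with a dilation of the resultant blob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage.filters import threshold_multiotsu
from skimage.morphology import dilation, disk

from .errors import DegenerateInputError, ParameterError, ValidationError
from .fusion import ResultantBlob

Z_DEFAULT = 1.96  # 95% two-sided normal quantile


def image_std(image: np.ndarray) -> float:
    """Population standard deviation over all pixels."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValidationError("empty image")
    return float(image.std())


def _quadrant_slices(shape: tuple[int, int]):
    """Row/col slices of the four quadrants (TL, TR, BL, BR); the split
    is at floor(n/2), so odd dimensions put the extra row/col in the
    bottom/right quadrants."""
    r, c = shape[0] // 2, shape[1] // 2
    return [
        (slice(0, r), slice(0, c)),
        (slice(0, r), slice(c, None)),
        (slice(r, None), slice(0, c)),
        (slice(r, None), slice(c, None)),
    ]


def quadrant_means(image: np.ndarray) -> np.ndarray:
    """Mean intensity of each quadrant, ordered TL, TR, BL, BR."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise ValidationError(f"image must be at least 2x2, got {image.shape}")
    return np.array([image[rs, cs].mean() for rs, cs in _quadrant_slices(image.shape)])


def ci_bounds(mean: float, sigma: float, z: float = Z_DEFAULT) -> tuple[float, float]:
    """Confidence band (A1, A2) = (ā − z·σ, ā + z·σ)."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    return mean - z * sigma, mean + z * sigma


@dataclass
class ConfidenceBounds:
    """Per-quadrant means with the shared-σ confidence band."""

    quadrant_means: np.ndarray  # (4,)
    sigma: float
    lower: np.ndarray  # A1 per quadrant
    upper: np.ndarray  # A2 per quadrant
    z: float = Z_DEFAULT

    @classmethod
    def from_image(cls, image: np.ndarray, z: float = Z_DEFAULT) -> "ConfidenceBounds":
        means = quadrant_means(image)
        sigma = image_std(image)
        pairs = [ci_bounds(m, sigma, z) for m in means]
        lower = np.array([p[0] for p in pairs])
        upper = np.array([p[1] for p in pairs])
        return cls(quadrant_means=means, sigma=sigma, lower=lower, upper=upper, z=z)


def remap_pixels(image: np.ndarray, bounds: ConfidenceBounds) -> np.ndarray:
    """Apply the three-band confidence-interval rule per quadrant.

    For a pixel p in quadrant q with mean ā_q and lower bound A1_q:
    p ≥ ā_q → p;  A1_q ≤ p < ā_q → min(1, p + ā_q);  p < A1_q → ā_q.
    Never decreases a pixel below min(p, ā_q).
    """
    image = np.asarray(image, dtype=np.float64)
    out = image.copy()
    for (rs, cs), mean, a1 in zip(_quadrant_slices(image.shape),
                                  bounds.quadrant_means, bounds.lower):
        block = image[rs, cs]
        mid = (block >= a1) & (block < mean)
        low = block < a1
        res = block.copy()
        res[mid] = np.minimum(1.0, block[mid] + mean)
        res[low] = mean
        out[rs, cs] = res
    return out


def dwt_smooth(image: np.ndarray) -> np.ndarray:
    """Single-level 2-D Haar smoothing: zero the detail coefficients,
    reconstruct, clip to [0, 1].  Output shape equals input shape."""
    image = np.asarray(image, dtype=np.float64)
    approx, (ch, cv, cd) = pywt.dwt2(image, "haar")
    rec = pywt.idwt2((approx, (np.zeros_like(ch), np.zeros_like(cv),
                               np.zeros_like(cd))), "haar")
    rec = rec[: image.shape[0], : image.shape[1]]
    return np.clip(rec, 0.0, 1.0)


def multi_threshold(image: np.ndarray, classes: int = 3) -> np.ndarray:
    """Multi-level Otsu labels 0..classes−1 in ascending intensity order."""
    image = np.asarray(image, dtype=np.float64)
    if classes < 2:
        raise ParameterError("need at least 2 classes")
    if np.unique(image).size < classes:
        raise DegenerateInputError(
            f"image has fewer than {classes} distinct values"
        )
    thresholds = threshold_multiotsu(image, classes=classes)
    return np.digitize(image, thresholds)


@dataclass
class ConfidenceRegion:
    """Output of the confidence transform."""

    remapped: np.ndarray
    bounds: ConfidenceBounds
    class_labels: np.ndarray
    mask: np.ndarray


def confidence_region(image: np.ndarray, resultant: ResultantBlob, *,
                      use_remap: bool = True, use_dwt: bool = True,
                      classes: int = 3, z: float = Z_DEFAULT,
                      dilate_radius: int = 6) -> ConfidenceRegion:
    """Full transform of the score image into the confidence region.

    The final mask is the highest-intensity Otsu class intersected with
    a dilation (default radius = the 13×13 kernel radius) of the
    resultant blob; an empty resultant blob yields an empty mask.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != resultant.mask.shape:
        raise ValidationError("image and resultant blob shapes differ")
    bounds = ConfidenceBounds.from_image(image, z)
    work = remap_pixels(image, bounds) if use_remap else image
    if use_dwt:
        work = dwt_smooth(work)
    if not resultant.mask.any():
        empty = np.zeros(image.shape, dtype=bool)
        return ConfidenceRegion(remapped=work, bounds=bounds,
                                class_labels=np.zeros(image.shape, dtype=int),
                                mask=empty)
    labels = multi_threshold(work, classes)
    top = labels == classes - 1
    dilated = dilation(resultant.mask, disk(dilate_radius))
    return ConfidenceRegion(remapped=work, bounds=bounds, class_labels=labels,
                            mask=top & dilated)
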