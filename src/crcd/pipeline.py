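"""End-to-end CRCD segmentation: adjust -> blobs -> fuse -> RSF -> CI region.

``segment_volume`` runs the whole method on a co-registered slice
stack.  The per-slice biggest blobs are fused per pattern and across
patterns into the resultant biggest blob (confidence score); the
RSF level set refines its boundary; the confidence-interval transform
turns the score image into the final confidence-region mask.  The
score image is the maximum-intensity projection of the adjusted
slices, so each pixel carries the brightest evidence any slice offers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confidence import ConfidenceRegion, confidence_region
from .fusion import PALETTE, PatternGroup, ResultantBlob, combine_blobs, group_slices, pattern_blob
from .io import GreyVolume, MaskVolume
from .levelset import Delineation, RSFParams, delineate
from .metrics import EvalReport
from .preprocess import AdjustParams, adjust_intensity


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one volume."""

    resultant: ResultantBlob
    delineation: Delineation
    region: ConfidenceRegion
    score_image: np.ndarray  # adjusted maximum-intensity projection

    @property
    def mask(self) -> np.ndarray:
        """Final binary tumour mask (the confidence region)."""
        return self.region.mask

    @property
    def confidence_score(self) -> int:
        return self.resultant.confidence_score


def segment_volume(volume: GreyVolume,
                   pattern_ranges: list[tuple[int, int]] | None = None,
                   adjust: AdjustParams = AdjustParams(),
                   threshold: float | str = "auto",
                   connectivity: int = 8,
                   rsf: RSFParams = RSFParams(),
                   use_remap: bool = True,
                   use_dwt: bool = True,
                   classes: int = 3,
                   z: float = 1.96) -> SegmentationResult:
    """Run the full CRCD method on a volume.

    ``pattern_ranges`` are inclusive slice ranges in source numbering;
    by default one pattern covers the whole volume.
    """
    if pattern_ranges is None:
        off = volume.slice_offset
        pattern_ranges = [(off, off + volume.n_slices - 1)]
    groups = group_slices(volume, pattern_ranges)
    patterns = [
        pattern_blob(g, adjust, threshold, connectivity,
                     color=PALETTE[i % len(PALETTE)])
        for i, g in enumerate(groups)
    ]
    resultant = combine_blobs(patterns)

    score_image = np.max(
        np.stack([adjust_intensity(sl, adjust) for sl in volume.data]), axis=0)

    delineation = delineate(score_image, resultant.mask, rsf)
    region = confidence_region(score_image, resultant,
                               use_remap=use_remap, use_dwt=use_dwt,
                               classes=classes, z=z,
                               dilate_radius=rsf.kernel_size // 2)
    return SegmentationResult(resultant=resultant, delineation=delineation,
                              region=region, score_image=score_image)


def truth_union(truth: MaskVolume) -> np.ndarray:
    """Fused 2-D ground truth: a pixel is tumour if any slice marks it.

    This is the reference the fused resultant blob and the final
    confidence region are compared against.
    """
    return truth.data.any(axis=0)


def evaluate_segmentation(result: SegmentationResult,
                          truth: MaskVolume) -> EvalReport:
    """Score the final mask against the fused ground truth."""
    return EvalReport.from_masks(result.mask, truth_union(truth))
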