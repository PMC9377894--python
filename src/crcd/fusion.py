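"""Pattern grouping and biggest-blob fusion.

Consecutive slices of a tumour volume share an intensity "pattern"
(e.g. slices 65-69 vs 70-74 of a BraTS patient).  Each pattern
contributes the union of its per-slice biggest blobs; fusing the
patterns pixelwise yields the *resultant biggest blob*, whose pixel
count is the confidence score.  An RGB overlay records which pattern
contributed each pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blobs import biggest_blob, binarize, label_components
from .errors import DegenerateInputError, EmptySelectionError, ParameterError, ValidationError
from .io import GreyVolume
from .preprocess import AdjustParams, adjust_intensity

#: Deterministic palette; assigned to patterns in order.
PALETTE: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0), (0, 255, 0), (0, 0, 255),
    (255, 255, 0), (255, 0, 255), (0, 255, 255),
    (255, 128, 0), (128, 0, 255),
)


@dataclass
class SliceGroup:
    """Slices of one intensity pattern, in source numbering."""

    slice_range: tuple[int, int]
    data: np.ndarray  # (n, rows, cols)


@dataclass
class PatternGroup:
    """Fused biggest blob of one pattern plus its overlay colour."""

    slice_range: tuple[int, int]
    pattern_blob: np.ndarray
    color: tuple[int, int, int]

    @property
    def area(self) -> int:
        return int(self.pattern_blob.sum())


@dataclass
class ResultantBlob:
    """Union of the per-pattern blobs with provenance and score."""

    mask: np.ndarray
    per_pattern: list[PatternGroup]
    overlay: np.ndarray  # (rows, cols, 3) uint8
    confidence_score: int


def group_slices(volume: GreyVolume, ranges: list[tuple[int, int]]) -> list[SliceGroup]:
    """Split a volume into pattern groups by inclusive source-numbered ranges.

    Ranges must be pairwise disjoint and lie inside the volume extent.
    """
    lo = volume.slice_offset
    hi = lo + volume.n_slices - 1
    seen: set[int] = set()
    groups = []
    for start, end in ranges:
        if start > end:
            raise ParameterError(f"range ({start}, {end}) has start > end")
        if start < lo or end > hi:
            raise ParameterError(
                f"range ({start}, {end}) outside volume slices {lo}-{hi}"
            )
        span = set(range(start, end + 1))
        if span & seen:
            raise ParameterError(f"range ({start}, {end}) overlaps another range")
        seen |= span
        groups.append(SliceGroup((start, end), volume.data[start - lo:end - lo + 1]))
    return groups


def pattern_blob(group: SliceGroup, adjust: AdjustParams = AdjustParams(),
                 threshold: float | str = "auto", connectivity: int = 8,
                 color: tuple[int, int, int] = PALETTE[0]) -> PatternGroup:
    """Biggest blob of a pattern: per slice adjust -> binarize -> label ->
    biggest blob, then union across the group's slices.

    Slices with no components (blank after thresholding) are skipped;
    if *every* slice is blank the pattern is empty and an
    :class:`EmptySelectionError` is raised.
    """
    if group.data.shape[0] == 0:
        raise ParameterError("empty slice group")
    union = np.zeros(group.data.shape[1:], dtype=bool)
    found = False
    for sl in group.data:
        adj = adjust_intensity(sl, adjust)
        try:
            mask = binarize(adj, threshold)
        except DegenerateInputError:
            continue
        labeling = label_components(mask, connectivity)
        if labeling.n_components == 0:
            continue
        union |= biggest_blob(labeling)
        found = True
    if not found:
        raise EmptySelectionError(
            f"no blobs found in any slice of pattern {group.slice_range}"
        )
    return PatternGroup(group.slice_range, union, color)


def combine_blobs(patterns: list[PatternGroup]) -> ResultantBlob:
    """Fuse pattern blobs into the resultant biggest blob.

    The mask is the pixelwise union; the confidence score is its pixel
    count; the overlay paints each pattern with its colour, later
    patterns overwriting earlier ones where they overlap.
    """
    if not patterns:
        raise ParameterError("need at least one pattern")
    shape = patterns[0].pattern_blob.shape
    for p in patterns[1:]:
        if p.pattern_blob.shape != shape:
            raise ValidationError("pattern blobs have mismatched shapes")
    mask = np.zeros(shape, dtype=bool)
    overlay = np.zeros(shape + (3,), dtype=np.uint8)
    for p in patterns:
        mask |= p.pattern_blob
        overlay[p.pattern_blob] = p.color
    return ResultantBlob(mask=mask, per_pattern=list(patterns), overlay=overlay,
                         confidence_score=int(mask.sum()))


@dataclass
class OverlapResult:
    """Decomposition of prediction vs ground truth."""

    intersection: np.ndarray
    pred_only: np.ndarray
    truth_only: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            "intersection": int(self.intersection.sum()),
            "pred_only": int(self.pred_only.sum()),
            "truth_only": int(self.truth_only.sum()),
        }


def overlap_with_truth(resultant: ResultantBlob, truth: np.ndarray) -> OverlapResult:
    """Split prediction and ground truth into overlap / pred-only / truth-only."""
    truth = np.asarray(truth).astype(bool)
    if truth.shape != resultant.mask.shape:
        raise ValidationError(
            f"truth shape {truth.shape} != prediction shape {resultant.mask.shape}"
        )
    pred = resultant.mask
    return OverlapResult(intersection=pred & truth,
                         pred_only=pred & ~truth,
                         truth_only=truth & ~pred)
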