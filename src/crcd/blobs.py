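"""Thresholding, connected-component labelling and biggest-blob selection.

A "blob" is a connected component of the binarized slice; the biggest
blob (maximal pixel area) is the tumour-region candidate.  Components
are labelled under 8-connectivity by default — diagonal neighbours
belong to the same blob — and labels are renumbered in raster-scan
order of first encounter so the labelling is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, EmptySelectionError, ParameterError


@dataclass
class Labeling:
    """Integer label image plus per-label areas and priority ranks.

    ``labels`` uses 0 for background and contiguous positive integers
    for components.  ``weights`` is a dense rank by area (1 = biggest);
    equal areas share a rank.
    """

    labels: np.ndarray
    areas: dict[int, int]
    weights: dict[int, int]

    @property
    def n_components(self) -> int:
        return len(self.areas)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


def binarize(slice_: np.ndarray, threshold: float | str = "auto") -> np.ndarray:
    """Threshold a [0, 1] slice; ``mask = slice >= threshold``.

    ``threshold="auto"`` picks the value maximizing between-class
    variance (Otsu).  A constant slice has no such value and raises
    :class:`DegenerateInputError`.
    """
    arr = np.asarray(slice_, dtype=np.float64)
    if threshold == "auto":
        if np.ptp(arr) == 0.0:
            raise DegenerateInputError("constant slice: automatic threshold undefined")
        threshold = float(threshold_otsu(arr))
    elif not isinstance(threshold, (int, float)):
        raise ParameterError(f"threshold must be a number or 'auto', got {threshold!r}")
    return arr >= float(threshold)


def _raster_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n in raster-scan order of first encounter."""
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    fg = uniq != 0
    uniq, first = uniq[fg], first[fg]
    order = uniq[np.argsort(first)]
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    lut[order] = np.arange(1, order.size + 1)
    return lut[labels]


def label_components(mask: np.ndarray, connectivity: int = 8) -> Labeling:
    """Label connected components of a binary mask (4- or 8-connected)."""
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    raw = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    labels = _raster_relabel(raw)
    counts = np.bincount(labels.ravel())
    areas = {int(lab): int(counts[lab]) for lab in range(1, counts.size)}
    # dense rank by area, 1 = biggest, ties share a rank
    distinct = sorted(set(areas.values()), reverse=True)
    rank = {a: i + 1 for i, a in enumerate(distinct)}
    weights = {lab: rank[a] for lab, a in areas.items()}
    return Labeling(labels=labels, areas=areas, weights=weights)


def biggest_blob(labeling: Labeling) -> np.ndarray:
    """Mask of the maximal-area component; ties go to the smallest label."""
    if labeling.n_components == 0:
        raise EmptySelectionError("no connected components to select from")
    best = min(labeling.areas, key=lambda lab: (-labeling.areas[lab], lab))
    return labeling.mask_of(best)
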