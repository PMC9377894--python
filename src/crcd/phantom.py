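"""Synthetic MRI-like tumour phantoms with ground truth.

The phantom emulates the structure the pipeline exploits on real data:
a dark background, an elliptical "brain" of textured tissue, and a
bright tumour disc with a linear intensity-falloff rim (the enhancing
core blending into tissue).  The tumour centre drifts slice to slice
and the drift direction flips halfway, producing two pattern groups
whose fused blob is a strict superset of any single-slice blob.
Additive Gaussian noise (clipped to [0, 1]) completes the picture.
All randomness is seeded, so a spec reproduces bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import GreyVolume, MaskVolume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic tumour volume.

    Intensities: core 0.85 falling linearly over ``rim_width`` px to
    tissue 0.45, on background 0.05.  The truth mask is the full disc
    including the rim.  ``pattern_split`` slices drift one way, the
    rest drift back the other way (two pattern groups).
    """

    shape: tuple[int, int, int] = (10, 128, 128)
    tumour_center: tuple[float, float] = (64.0, 64.0)
    tumour_radius: float = 12.0
    core_intensity: float = 0.85
    rim_width: float = 3.0
    tissue_intensity: float = 0.45
    background_intensity: float = 0.05
    drift_per_slice: float = 1.0
    pattern_split: int = 5
    noise_sigma: float = 0.02
    seed: int = 0
    slice_offset: int = 65

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_intensity < self.tissue_intensity
                < self.core_intensity <= 1.0):
            raise ParameterError("need background < tissue < core, all in [0, 1]")
        if self.tumour_radius <= 0 or self.rim_width < 0:
            raise ParameterError("tumour_radius must be > 0 and rim_width >= 0")
        if not 0 < self.pattern_split < self.shape[0]:
            raise ParameterError("pattern_split must cut the stack into two groups")

    def center_at(self, s: int) -> tuple[float, float]:
        """Tumour centre in slice ``s`` (0-based): the column drifts
        outward in the first group and back past the origin in the
        second, flipping direction at ``pattern_split``."""
        row, col = self.tumour_center
        if s < self.pattern_split:
            return row, col + self.drift_per_slice * s
        return row, col - self.drift_per_slice * (s - self.pattern_split + 1)


@dataclass
class PhantomOutput:
    """Volume, per-slice truth and the two pattern ranges (source numbering)."""

    volume: GreyVolume
    truth: MaskVolume
    pattern_ranges: list[tuple[int, int]]


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomOutput:
    """Render the phantom volume and its ground-truth mask."""
    n, rows, cols = spec.shape
    outer = spec.tumour_radius + spec.rim_width
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)

    # elliptical brain on dark background
    ec_r, ec_c = (rows - 1) / 2.0, (cols - 1) / 2.0
    brain = (((rr - ec_r) / (0.42 * rows)) ** 2
             + ((cc - ec_c) / (0.38 * cols)) ** 2) <= 1.0

    vol = np.empty((n, rows, cols), dtype=np.float64)
    truth = np.zeros((n, rows, cols), dtype=np.uint8)
    for s in range(n):
        crow, ccol = spec.center_at(s)
        if (crow - outer < 0 or crow + outer > rows - 1
                or ccol - outer < 0 or ccol + outer > cols - 1):
            raise ParameterError(f"tumour leaves the frame on slice {s}")
        d = np.hypot(rr - crow, cc - ccol)
        sl = np.where(brain, spec.tissue_intensity, spec.background_intensity)
        if spec.rim_width > 0:
            rim_frac = np.clip((d - spec.tumour_radius) / spec.rim_width, 0.0, 1.0)
        else:
            rim_frac = (d > spec.tumour_radius).astype(np.float64)
        tumour_val = (spec.core_intensity
                      + rim_frac * (spec.tissue_intensity - spec.core_intensity))
        inside = d <= outer
        sl = np.where(inside, tumour_val, sl)
        sl = sl + rng.normal(0.0, spec.noise_sigma, size=sl.shape)
        vol[s] = np.clip(sl, 0.0, 1.0)
        truth[s] = inside.astype(np.uint8)

    off = spec.slice_offset
    ranges = [(off, off + spec.pattern_split - 1), (off + spec.pattern_split, off + n - 1)]
    return PhantomOutput(
        volume=GreyVolume(vol, slice_offset=off, source_path=f"phantom(seed={spec.seed})"),
        truth=MaskVolume(truth, slice_offset=off, source_path=f"phantom(seed={spec.seed})"),
        pattern_ranges=ranges,
    )


@dataclass
class WorkedExample:
    """Tiny hand-built slice with frozen expected intermediates.

    All intensities are dyadic rationals so every statistic below is
    exact in float64.  The expected values were computed once with
    brute-force reference code (flood fill, index-range accumulation,
    two-pass statistics) and frozen here.
    """

    slice: np.ndarray
    threshold: float
    mask: np.ndarray
    labels: np.ndarray
    areas: dict[int, int]
    biggest_label: int
    truth: np.ndarray
    quadrant_means: np.ndarray
    sigma: float
    lower: np.ndarray   # A1 per quadrant
    upper: np.ndarray   # A2 per quadrant
    remapped: np.ndarray
    dice: float


def make_worked_example() -> WorkedExample:
    """8×8 slice: one 6-px blob, one 15-px blob (biggest, with a dark
    hole pixel), one isolated pixel; plus the frozen expected outputs
    of binarize / label / biggest-blob / quadrant stats / CI remap."""
    sl = np.full((8, 8), 0.125)
    sl[0:2, 0:3] = 0.875          # blob 1, area 6
    sl[4:8, 4:8] = 0.75           # blob 2, area 15 after the hole
    sl[6, 1] = 0.9375             # blob 3, area 1
    sl[4, 4] = 0.0                # dark hole: exercises the below-A1 band

    mask = sl >= 0.5
    labels = np.zeros((8, 8), dtype=int)
    labels[0:2, 0:3] = 1
    labels[4:8, 4:8] = 2
    labels[4, 4] = 0
    labels[6, 1] = 3
    truth = np.zeros((8, 8), dtype=bool)
    truth[4:8, 3:8] = True        # 20 px; biggest blob covers 15 of them

    q_means = np.array([0.40625, 0.125, 0.17578125, 0.703125])
    sigma = 0.3210485421908517    # sqrt(0.1030721664428711), population SD
    lower = np.array([-0.22300514269406935, -0.5042551426940693,
                      -0.45347389269406935, 0.07386985730593065])
    upper = np.array([1.0355051426940693, 0.7542551426940693,
                      0.8050363926940693, 1.3323801426940693])

    remapped = sl.copy()
    remapped[0:4, 0:4][sl[0:4, 0:4] == 0.125] = 0.53125        # 0.125 + 0.40625
    remapped[4:8, 0:4][sl[4:8, 0:4] == 0.125] = 0.30078125     # 0.125 + 0.17578125
    remapped[4, 4] = 0.703125                                  # below A1 -> quadrant mean
    # TR quadrant is constant at its mean -> kept; 0.75/0.875/0.9375 >= mean -> kept

    return WorkedExample(
        slice=sl, threshold=0.5, mask=mask, labels=labels,
        areas={1: 6, 2: 15, 3: 1}, biggest_label=2, truth=truth,
        quadrant_means=q_means, sigma=sigma, lower=lower, upper=upper,
        remapped=remapped, dice=0.8571428571428571,  # 2*15 / (15+20)
    )
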