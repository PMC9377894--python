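"""Segmentation evaluation: Dice, Jaccard, MSE and PSNR.

Dice (DOI) and Jaccard (JI) compare binary masks; both are defined as
1.0 when prediction and truth are both empty (perfect agreement on
"nothing there").  MSE and PSNR compare [0, 1]-scaled images with a
default peak of 1.0; identical images give MSE 0 and an infinite PSNR.
The Dice-Jaccard identity D = 2J/(1+J) holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap index 2|A∩B| / (|A|+|B|); 1.0 when both empty."""
    pred, truth = _check_shapes(pred, truth)
    a, b = pred.astype(bool), truth.astype(bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both empty."""
    pred, truth = _check_shapes(pred, truth)
    a, b = pred.astype(bool), truth.astype(bool)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def mse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error between two intensity images."""
    pred, truth = _check_shapes(pred, truth)
    diff = pred.astype(np.float64) - truth.astype(np.float64)
    return float(np.mean(diff ** 2))


def psnr(pred: np.ndarray, truth: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10·log10(peak²/MSE) in dB; +inf at MSE 0."""
    err = mse(pred, truth)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak ** 2 / err)


@dataclass
class EvalReport:
    """The four evaluation measures for one prediction/truth pair."""

    doi: float
    ji: float
    mse: float
    psnr: float

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray,
                   peak: float = 1.0) -> "EvalReport":
        """Evaluate binary masks, treating them as [0, 1] images for
        the intensity measures."""
        p = np.asarray(pred).astype(np.float64)
        t = np.asarray(truth).astype(np.float64)
        return cls(doi=dice(pred, truth), ji=jaccard(pred, truth),
                   mse=mse(p, t), psnr=psnr(p, t, peak))

    def as_row(self, name: str) -> str:
        ps = "inf" if math.isinf(self.psnr) else f"{self.psnr:.4f}"
        return f"{name},{self.doi:.4f},{self.ji:.4f},{self.mse:.6f},{ps}"
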