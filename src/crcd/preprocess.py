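"""Linear intensity adjustment (window stretch).

Tumour tissue on contrast-enhanced MRI occupies a narrow bright band of
the normalized intensity range; stretching the window [low_in, high_in]
onto [0, 1] separates it from normal tissue before blob detection.  The
default window is 0.36-0.78, the band in which enhancing-tumour
intensities concentrate on BraTS-style T1 sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class AdjustParams:
    """Window-stretch parameters; gain/offset derive from the window.

    The adjusted value is ``clip(alpha * x + beta, 0, 1)`` with
    ``alpha = 1 / (high_in - low_in)`` and ``beta = -low_in * alpha``,
    i.e. ``low_in -> 0`` and ``high_in -> 1``.
    """

    low_in: float = 0.36
    high_in: float = 0.78

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_in < self.high_in <= 1.0):
            raise ParameterError(
                f"need 0 <= low_in < high_in <= 1, got ({self.low_in}, {self.high_in})"
            )

    @property
    def alpha(self) -> float:
        return 1.0 / (self.high_in - self.low_in)

    @property
    def beta(self) -> float:
        return -self.low_in * self.alpha


def adjust_intensity(slice_: np.ndarray, params: AdjustParams = AdjustParams()) -> np.ndarray:
    """Apply the linear window stretch to a [0, 1] slice.

    Monotone non-decreasing in the input; with ``low_in=0, high_in=1``
    it is the identity.
    """
    x = np.asarray(slice_, dtype=np.float64)
    return np.clip(params.alpha * x + params.beta, 0.0, 1.0)
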