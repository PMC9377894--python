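"""Volume and mask containers plus NIfTI / image-stack I/O.

The pipeline works on ordered stacks of co-registered 2-D greyscale
slices.  Intensities are always normalized to [0, 1] on ingest; the
slice axis is the *last* NIfTI axis (BraTS convention) and is moved to
the front so arrays are indexed ``(slice, row, col)``.  ``slice_offset``
lets callers address slices in the source numbering (e.g. the
tumour-visible window 65-74 of a 155-slice BraTS volume).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError, ValidationError

_INT16_MAX = np.float64(65535.0)


@dataclass
class GreyVolume:
    """Ordered stack of 2-D greyscale slices with intensities in [0, 1].

    Parameters
    ----------
    data:
        Array of shape ``(slices, rows, cols)`` with values in [0, 1].
    slice_offset:
        Source index of the first slice, so ``volume.slice_at(k)``
        addresses slices by their original numbering.
    source_path:
        Provenance string (file the volume was loaded from, or a tag).
    """

    data: np.ndarray
    slice_offset: int = 0
    source_path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValidationError("volume must be a non-empty (slice, row, col) stack")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains NaN or Inf")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValidationError("volume intensities must lie in [0, 1]")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_numbers(self) -> range:
        """Source numbering of the slices in this volume."""
        return range(self.slice_offset, self.slice_offset + self.n_slices)

    def slice_at(self, number: int) -> np.ndarray:
        """Return the 2-D slice addressed by its *source* number."""
        idx = number - self.slice_offset
        if not 0 <= idx < self.n_slices:
            raise ValidationError(
                f"slice {number} outside volume range {self.slice_numbers}"
            )
        return self.data[idx]


@dataclass
class MaskVolume:
    """Binary label stack paired with a :class:`GreyVolume` (same shape)."""

    data: np.ndarray
    slice_offset: int = 0
    source_path: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValidationError("mask must be a non-empty (slice, row, col) stack")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mask values must be 0/1")
        self.data = arr.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def check_matches(self, volume: GreyVolume) -> None:
        if self.data.shape != volume.data.shape:
            raise ValidationError(
                f"mask shape {self.data.shape} != volume shape {volume.data.shape}"
            )


def normalize(raw: np.ndarray, *, slice_offset: int = 0, source_path: str = "") -> GreyVolume:
    """Min-max scale an arbitrary numeric stack to [0, 1].

    A constant input maps to all zeros (the degenerate-range rule).
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if not np.all(np.isfinite(arr)):
        raise ValidationError("input contains NaN or Inf")
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return GreyVolume(arr, slice_offset=slice_offset, source_path=source_path)


def _scale_on_load(arr: np.ndarray, dtype: np.dtype) -> np.ndarray:
    # Integer data is scaled by its dtype range so save/load round-trips;
    # float data falls back to min-max normalization.
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("volume contains NaN or Inf")
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(arr / float(info.max), 0.0, 1.0)
    lo, hi = arr.min(), arr.max()
    if 0.0 <= lo and hi <= 1.0:
        return arr
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


_STACK_EXTS = (".png", ".tif", ".tiff")


def load_volume(path: str | os.PathLike, format: str | None = None,
                slice_offset: int = 0) -> GreyVolume:
    """Read a greyscale volume from NIfTI or a directory of 2-D images.

    ``format`` is ``"nifti"``, ``"image_stack"`` or ``None`` (inferred
    from the path).  Image stacks are read in sorted filename order;
    RGB(A) slices are collapsed to grey by channel mean.
    """
    import nibabel as nib

    p = Path(path)
    if format is None:
        format = "image_stack" if p.is_dir() else "nifti"

    if format == "nifti":
        try:
            img = nib.load(str(p))
            raw = np.asanyarray(img.dataobj)
        except Exception as exc:  # nibabel raises a zoo of error types
            raise FormatError(f"cannot read {p} as NIfTI: {exc}") from exc
        if raw.ndim == 2:
            raw = raw[..., None]
        if raw.ndim != 3 or raw.shape[-1] < 1 or raw.size == 0:
            raise ValidationError(f"{p}: expected a 3-D volume, got shape {raw.shape}")
        data = np.transpose(raw, (2, 0, 1))  # slice axis last -> first
        scaled = _scale_on_load(data, raw.dtype)
        return GreyVolume(scaled, slice_offset=slice_offset, source_path=str(p))

    if format == "image_stack":
        import imageio.v3 as iio

        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _STACK_EXTS) \
            if p.is_dir() else [p]
        if not files:
            raise ValidationError(f"{p}: no PNG/TIFF slices found")
        slices = []
        for f in files:
            try:
                im = np.asarray(iio.imread(f))
            except Exception as exc:
                raise FormatError(f"cannot read {f} as an image: {exc}") from exc
            if im.ndim == 3:
                im = im.mean(axis=-1).astype(im.dtype)
            slices.append(_scale_on_load(im, np.asarray(iio.imread(f)).dtype))
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValidationError(f"{p}: slices have mixed shapes {shapes}")
        return GreyVolume(np.stack(slices), slice_offset=slice_offset,
                          source_path=str(p))

    raise ParameterError(f"unknown format {format!r}")


def save_volume(volume: GreyVolume, path: str | os.PathLike) -> None:
    """Write a volume as 16-bit NIfTI (slice axis restored to last)."""
    import nibabel as nib

    data = np.transpose(np.round(volume.data * _INT16_MAX).astype(np.uint16),
                        (1, 2, 0))
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))


def save_mask(mask: MaskVolume, path: str | os.PathLike) -> None:
    """Write a binary mask as 8-bit NIfTI labels."""
    import nibabel as nib

    data = np.transpose(mask.data.astype(np.uint8), (1, 2, 0))
    try:
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    except Exception as exc:
        raise FormatError(f"cannot write mask to {path}: {exc}") from exc


def load_mask(path: str | os.PathLike, slice_offset: int = 0) -> MaskVolume:
    """Read a label volume and binarize it (any nonzero label -> 1)."""
    import nibabel as nib

    try:
        img = nib.load(str(path))
        raw = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if raw.ndim == 2:
        raw = raw[..., None]
    data = np.transpose(raw, (2, 0, 1))
    return MaskVolume((data > 0).astype(np.uint8), slice_offset=slice_offset,
                      source_path=str(path))
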