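"""Seedling-scale voxelwise ratio images.

Two complementary readouts of the same two-channel stack, both computed
after max-matching normalization of the DII channel against mDII:

* negative protocol — DII / mDII under a binary mask derived from the mDII
  channel; low values mean high auxin sensing. Values are <= 1 up to noise,
  stored as 32-bit float, zero outside the mask.
* positive protocol — mDII / DII under an intensity-threshold nuclear mask
  applied multiplicatively, so non-nuclear voxels and low-auxin cells sit
  near zero; high values mean high auxin sensing.

Inside the intersection of both masks the two protocols are exact
reciprocals of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .stack import ImageStack

__all__ = ["RatioImage", "ratio_image_negative", "ratio_image_positive"]


@dataclass
class RatioImage:
    """Voxelwise ratio volume (32-bit float), zero outside its mask."""

    values: np.ndarray
    protocol: str  # "neg" (DII/mDII) or "pos" (mDII/DII)
    mask: np.ndarray
    mask_note: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def write_series(self, out_dir) -> None:
        """Export as a per-slice 32-bit TIFF series plus one multipage TIFF."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for z in range(self.values.shape[0]):
            tifffile.imwrite(out / f"ratio_{self.protocol}_z{z:03d}.tif", self.values[z])
        tifffile.imwrite(out / f"ratio_{self.protocol}_stack.tif", self.values)


def _normalize_max_match(dii: np.ndarray, mdii: np.ndarray) -> np.ndarray:
    """Rescale DII so max(DII) == max(mDII) over the whole volume."""
    max_dii = float(dii.max())
    max_mdii = float(mdii.max())
    if max_dii <= 0:
        raise ValueError("DII channel is all zero; cannot normalize")
    return dii * (max_mdii / max_dii)


def ratio_image_negative(
    dii, mdii, mask: np.ndarray | None = None
) -> RatioImage:
    """DII / mDII ratio image (negative auxin readout).

    DII is normalized so the channel maxima match, a binary mask is taken
    from the mDII channel (Otsu by default, or pass one explicitly), both
    channels are masked, and the division is performed where the masked
    mDII is positive. Out-of-mask voxels are 0.
    """
    dii = np.asarray(dii, dtype=float)
    mdii = np.asarray(mdii, dtype=float)
    if dii.shape != mdii.shape:
        raise ValueError("channel shapes differ")
    if not mdii.any():
        raise ValueError("mDII channel is all zero")
    dii_n = _normalize_max_match(dii, mdii)
    if mask is None:
        thr = float(threshold_otsu(mdii))
        mask = mdii > thr
        note = f"otsu(mDII)={thr:.6g}"
    else:
        mask = np.asarray(mask, dtype=bool)
        note = "explicit mask"
    vals = np.zeros(dii.shape, dtype=np.float32)
    ok = mask & (mdii > 0)
    vals[ok] = (dii_n[ok] / mdii[ok]).astype(np.float32)
    return RatioImage(values=vals, protocol="neg", mask=mask, mask_note=note)


def ratio_image_positive(
    mdii, dii, nuclear_threshold: float | None = None, mask: np.ndarray | None = None
) -> RatioImage:
    """mDII / DII ratio image (positive auxin readout).

    After the same max-matching normalization, mDII is divided by the
    normalized DII; the raw ratio image is then segmented by an intensity
    threshold (Otsu on the ratio image when none is given) into a binary
    nuclear mask that multiplies the ratio image, zeroing everything
    outside nuclei. In-mask voxels where DII is 0 cannot be divided and are
    set to 0.
    """
    dii = np.asarray(dii, dtype=float)
    mdii = np.asarray(mdii, dtype=float)
    if dii.shape != mdii.shape:
        raise ValueError("channel shapes differ")
    if not mdii.any():
        raise ValueError("mDII channel is all zero")
    dii_n = _normalize_max_match(dii, mdii)
    raw = np.zeros(dii.shape, dtype=float)
    divisible = dii_n > 0
    raw[divisible] = mdii[divisible] / dii_n[divisible]
    if mask is None:
        if nuclear_threshold is None:
            if np.all(raw == raw.flat[0]):
                raise ValueError("ratio image constant; supply nuclear_threshold")
            nuclear_threshold = float(threshold_otsu(raw))
        mask = raw > nuclear_threshold
        note = f"threshold(ratio)={nuclear_threshold:.6g}"
    else:
        mask = np.asarray(mask, dtype=bool)
        note = "explicit mask"
    vals = np.where(mask & divisible, raw, 0.0).astype(np.float32)
    return RatioImage(values=vals, protocol="pos", mask=mask, mask_note=note)
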