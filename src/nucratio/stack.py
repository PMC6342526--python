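"""Core image containers.

Voxel data are kept in ``(z, y, x)`` axis order (optionally with a trailing
channel axis handled by :class:`ImageStack` as named single-channel views).
All physical coordinates and distances are expressed in micrometres via the
per-axis ``spacing``; confocal stacks are typically anisotropic (z-step
larger than the xy pixel size), and every distance-aware operation in this
package goes through the spacing rather than assuming cubic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageStack", "make_toy_volume"]


@dataclass
class ImageStack:
    """A 3D multi-channel intensity volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray
        Intensities, shape ``(z, y, x)`` for a single channel or
        ``(z, y, x, c)`` for multiple channels. Non-negative.
    spacing : tuple of float
        Physical voxel size ``(z, y, x)`` in micrometres.
    bit_depth : int
        Nominal acquisition bit depth (8, 12 or 16). Used for quantization
        bounds; the array dtype may be wider.
    channels : tuple of str
        Channel names, one per channel axis entry. A single-channel stack
        has one name.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 12
    channels: tuple[str, ...] = ("intensity",)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(
                f"expected a (z, y, x[, c]) array, got ndim={self.voxels.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        n_chan = self.voxels.shape[3] if self.voxels.ndim == 4 else 1
        if len(self.channels) != n_chan:
            raise ValueError(
                f"{n_chan} channel(s) in data but {len(self.channels)} name(s)"
            )
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("intensities must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)``."""
        return self.voxels.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[3] if self.voxels.ndim == 4 else 1

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array of one named channel (a view where possible)."""
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {self.channels}")
        if self.voxels.ndim == 3:
            return self.voxels
        return self.voxels[..., self.channels.index(name)]

    def with_voxels(self, voxels: np.ndarray, channels: tuple[str, ...] | None = None) -> "ImageStack":
        """Copy of this stack with new voxel data (same spacing / bit depth)."""
        return replace(
            self,
            voxels=voxels,
            channels=self.channels if channels is None else tuple(channels),
        )

    def max_value(self) -> int:
        """Largest representable intensity at this bit depth."""
        return 2 ** self.bit_depth - 1


def make_toy_volume(values, spacing=(1.0, 1.0, 1.0)) -> ImageStack:
    """Wrap a literal array as a single-channel :class:`ImageStack`.

    1D input is treated as a ``1 x 1 x N`` volume and 2D input as ``1 x M x N``,
    which makes hand-enumerable segmentation fixtures easy to write.
    Ragged nested sequences are rejected.
    """
    arr = np.asarray(values, dtype=float)
    if arr.dtype == object:
        raise ValueError("ragged input: voxel values must form a rectangular array")
    if arr.ndim == 1:
        arr = arr[np.newaxis, np.newaxis, :]
    elif arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    elif arr.ndim != 3:
        raise ValueError(f"expected 1-3 dims, got {arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("voxel values must be finite")
    return ImageStack(voxels=arr, spacing=spacing, bit_depth=16)
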