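"""3D volume and multichannel containers with NIfTI I/O.

All images in the package travel as :class:`Volume` (one 3D scalar array plus
a 4x4 voxel-to-world affine in mm) or :class:`ChannelStack` (several
co-registered volumes, one per acquisition channel).  The package performs no
resampling or registration anywhere: channels must arrive on an identical
grid, and :func:`stack_channels` rejects anything else rather than silently
interpolating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: maximum element-wise affine discrepancy (mm) tolerated between
#: "co-registered" grids
GRID_TOL = 1e-4


class GridMismatchError(ValueError):
    """Inputs do not share a common voxel grid (shape and affine)."""


@dataclass
class Volume:
    """A single 3D scalar image with grid geometry.

    Parameters
    ----------
    data
        3D array; physical units are whatever the acquisition produced.
    affine
        4x4 voxel-to-world transform in mm.  Voxel indices are 0-based.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all Volume dimensions must be >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes derived from affine must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with this grid and the given data."""
        return Volume(np.asarray(data), self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


def grids_compatible(a: Volume, b: Volume, tol: float = GRID_TOL) -> bool:
    return a.shape == b.shape and bool(
        np.all(np.abs(a.affine - b.affine) <= tol)
    )


def check_grid(a: Volume, b: Volume, tol: float = GRID_TOL) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    err = float(np.max(np.abs(a.affine - b.affine)))
    if err > tol:
        raise GridMismatchError(
            f"affines differ by up to {err:.3g} mm (> {tol:g}); inputs must be "
            "co-registered beforehand — this package never resamples"
        )


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1/2 image.

    The format's scale/intercept are applied; no other rescaling.  4D images
    are rejected here — multi-echo series go through
    :func:`multiseg.relaxometry.read_multi_echo`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(
            f"{path} is {data.ndim}D; expected a 3D image "
            "(use the multi-echo reader for echo series)"
        )
    return Volume(data, np.asarray(img.affine))


def write_volume(vol: Volume, path: str | Path, dtype=np.float32) -> Path:
    """Write a Volume as NIfTI; integer dtypes preserved for label maps."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.int16 if data.dtype.itemsize <= 2 else np.int32)
    else:
        out = data.astype(dtype)
    nib.save(nib.Nifti1Image(out, vol.affine), str(path))
    return path


@dataclass
class ChannelStack:
    """N co-registered channels per voxel, the input to segmentation.

    The optional ``mask`` marks voxels participating in model fitting.  When
    absent, every voxel finite in all channels participates; non-finite
    voxels are dropped with a logged count.
    """

    channels: list[Volume]
    channel_names: list[str]
    mask: Volume | None = None

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("at least one channel required")
        if len(self.channels) != len(self.channel_names):
            raise ValueError("one name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"duplicate channel names: {self.channel_names}")
        ref = self.channels[0]
        for vol in self.channels[1:]:
            check_grid(ref, vol)
        if self.mask is not None:
            check_grid(ref, self.mask)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def affine(self) -> np.ndarray:
        return self.channels[0].affine

    @property
    def grid(self) -> Volume:
        return self.channels[0]

    def channel(self, name: str) -> Volume:
        return self.channels[self.channel_names.index(name)]

    def effective_mask(self) -> np.ndarray:
        """Boolean array of voxels entering the fit (mask ∧ all-finite)."""
        finite = np.ones(self.shape, dtype=bool)
        for vol in self.channels:
            finite &= np.isfinite(vol.data)
        if self.mask is not None:
            base = self.mask.data.astype(bool)
        else:
            base = np.ones(self.shape, dtype=bool)
        out = base & finite
        dropped = int(base.sum() - out.sum())
        if dropped:
            logger.info("excluding %d non-finite voxels from mask", dropped)
        return out

    def samples(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_voxels, n_channels) data matrix and the flat indices used."""
        m = self.effective_mask()
        idx = np.flatnonzero(m.ravel())
        X = np.stack([v.data.ravel()[idx] for v in self.channels], axis=1)
        return X.astype(float), idx

    def subset(self, names: list[str]) -> "ChannelStack":
        """A stack restricted to the named channels, order preserved."""
        return ChannelStack(
            [self.channel(n) for n in names], list(names),
            self.mask.copy() if self.mask is not None else None,
        )


def stack_channels(
    volumes: list[Volume],
    names: list[str],
    mask: Volume | None = None,
) -> ChannelStack:
    """Assemble co-registered volumes into a ChannelStack.

    Raises :class:`GridMismatchError` when any pair of inputs differs in
    shape or affine beyond tolerance — the signature of un-co-registered
    inputs, which must be fixed upstream.
    """
    if len(volumes) != len(names):
        raise ValueError("volumes and names must have equal length")
    return ChannelStack(list(volumes), list(names), mask)
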