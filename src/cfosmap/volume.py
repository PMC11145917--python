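"""Volumetric containers, TIFF I/O and patch tiling/stitching.

Volumes are indexed ``(z, y, x)`` with 0-based voxel coordinates; physical
coordinates in micrometres are ``index * voxel_size``.  Light-sheet stacks of
the kind this package targets are strongly anisotropic (typically 1 x 1 x 3.5
um voxels), so every physical computation carries the per-axis voxel size.

Large volumes are processed patch-wise: :func:`tile_volume` cuts a volume into
core tiles that exactly partition it, each padded by a reflective halo so that
a segmentation model sees context across tile borders, and
:func:`stitch_masks` writes only the halo-cropped cores back, giving an exact
partition of the output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "IntensityVolume",
    "MaskVolume",
    "PatchSpec",
    "read_volume",
    "write_volume",
    "tile_volume",
    "stitch_masks",
]

_CHANNELS = ("signal", "autofluorescence")


@dataclass
class IntensityVolume:
    """One imaging channel: a 3D array of non-negative intensities (a.u.)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.5, 1.0, 1.0)  # (dz, dy, dx) um
    channel: str = "signal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive components, got {self.voxel_size}")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class MaskVolume:
    """Binary voxel-wise segmentation aligned to an :class:`IntensityVolume`."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.5, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")
            arr = arr.astype(np.uint8)
        elif arr.max(initial=0) > 1:
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive components, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass(frozen=True)
class PatchSpec:
    """Placement of one tile: core origin/shape in parent voxels plus halo width."""

    core_origin: tuple[int, int, int]
    core_shape: tuple[int, int, int]
    halo: int = 0

    def __post_init__(self) -> None:
        if self.halo < 0:
            raise ValueError(f"halo must be >= 0, got {self.halo}")
        if any(s < 1 for s in self.core_shape):
            raise ValueError(f"core_shape components must be >= 1, got {self.core_shape}")


def read_volume(
    path: str | os.PathLike,
    channel: str = "signal",
    voxel_size: tuple[float, float, float] = (3.5, 1.0, 1.0),
) -> IntensityVolume:
    """Read a multi-page TIFF stack (or a directory of per-plane TIFFs).

    For a directory, planes are ordered lexicographically by filename and must
    all share one shape. Pixel type must be integer (raw camera counts).
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        names = sorted(f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff")))
        if not names:
            raise FileNotFoundError(f"no TIFF planes found in directory {path}")
        planes = [tifffile.imread(os.path.join(path, n)) for n in names]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent plane shapes in {path}: {sorted(shapes)}")
        data = np.stack(planes, axis=0)
    elif os.path.isfile(path):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    else:
        raise FileNotFoundError(f"volume not found: {path}")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"expected an integer pixel type, got {data.dtype}")
    return IntensityVolume(data=data, voxel_size=voxel_size, channel=channel)


def write_volume(vol: IntensityVolume | MaskVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF."""
    tifffile.imwrite(os.fspath(path), np.asarray(vol.data))


def _as_triple(x) -> tuple[int, int, int]:
    if np.isscalar(x):
        return (int(x),) * 3
    t = tuple(int(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected scalar or 3 components, got {x!r}")
    return t


def tile_volume(
    vol: IntensityVolume | MaskVolume | np.ndarray,
    core_shape,
    halo: int = 0,
) -> list[tuple[PatchSpec, np.ndarray]]:
    """Cut a volume into core tiles plus a reflect-padded halo.

    The core tiles are disjoint and exactly cover the volume; border tiles are
    padded by reflection (both for cores overhanging the volume edge and for
    the halo), so every returned patch has shape ``core_shape + 2*halo``.
    """
    data = vol if isinstance(vol, np.ndarray) else vol.data
    core_shape = _as_triple(core_shape)
    if any(c < 1 for c in core_shape):
        raise ValueError(f"core_shape components must be >= 1, got {core_shape}")
    if halo < 0:
        raise ValueError(f"halo must be >= 0, got {halo}")

    shape = data.shape
    n_tiles = [int(np.ceil(shape[a] / core_shape[a])) for a in range(3)]
    # pad once: halo on the low side, halo + core overhang on the high side
    pad = [
        (halo, halo + n_tiles[a] * core_shape[a] - shape[a])
        for a in range(3)
    ]
    padded = _reflect_pad(data, pad)

    patches: list[tuple[PatchSpec, np.ndarray]] = []
    for iz in range(n_tiles[0]):
        for iy in range(n_tiles[1]):
            for ix in range(n_tiles[2]):
                origin = (iz * core_shape[0], iy * core_shape[1], ix * core_shape[2])
                sl = tuple(
                    slice(origin[a], origin[a] + core_shape[a] + 2 * halo)
                    for a in range(3)
                )
                clipped_core = tuple(
                    min(core_shape[a], shape[a] - origin[a]) for a in range(3)
                )
                spec = PatchSpec(core_origin=origin, core_shape=clipped_core, halo=halo)
                patches.append((spec, padded[sl].copy()))
    return patches


def _reflect_pad(data: np.ndarray, pad: list[tuple[int, int]]) -> np.ndarray:
    """Reflect-pad, repeating the edge further once reflection is exhausted."""
    out = data
    for axis, (lo, hi) in enumerate(pad):
        while lo > 0 or hi > 0:
            step_lo = min(lo, max(out.shape[axis] - 1, 1))
            step_hi = min(hi, max(out.shape[axis] - 1, 1))
            width = [(0, 0)] * 3
            width[axis] = (step_lo, step_hi)
            mode = "reflect" if out.shape[axis] > 1 else "edge"
            out = np.pad(out, width, mode=mode)
            lo -= step_lo
            hi -= step_hi
    return out


def stitch_masks(
    patches: list[tuple[PatchSpec, np.ndarray]],
    full_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (3.5, 1.0, 1.0),
) -> MaskVolume:
    """Reassemble halo-cropped patch cores into a full-volume mask.

    The specs must form a complete, non-overlapping tiling of ``full_shape``;
    each output voxel is written exactly once.
    """
    full_shape = tuple(int(s) for s in full_shape)
    out = np.zeros(full_shape, dtype=np.uint8)
    covered = np.zeros(full_shape, dtype=bool)
    for spec, patch in patches:
        h = spec.halo
        core = patch[tuple(slice(h, h + spec.core_shape[a]) for a in range(3))]
        sl = tuple(
            slice(spec.core_origin[a], spec.core_origin[a] + spec.core_shape[a])
            for a in range(3)
        )
        if covered[sl].any():
            raise ValueError(f"double coverage in tiling at core origin {spec.core_origin}")
        out[sl] = core
        covered[sl] = True
    if not covered.all():
        missing = np.argwhere(~covered)[0]
        raise ValueError(f"incomplete tiling: voxel {tuple(missing)} not covered")
    return MaskVolume(data=out, voxel_size=voxel_size)
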