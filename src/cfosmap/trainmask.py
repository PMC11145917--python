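"""Spot-like training-mask generation from raw signal volumes.

Ground-truth labels for the segmentation network are produced without manual
annotation: an intensity threshold is estimated from representative regions
of the volume (``mean + k * SD`` of the pooled voxel intensities), bright
local maxima above the threshold are detected with a physical minimum
separation, and each detected spot is rendered as a small ellipsoid (a fixed
radius in micrometres, converted per axis by the voxel size).  Image/mask
pairs are then tiled into model-input patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig
from .volume import IntensityVolume, MaskVolume, tile_volume

__all__ = [
    "ThresholdReport",
    "TrainingPair",
    "estimate_intensity_threshold",
    "detect_spots",
    "render_spot_mask",
    "build_training_set",
]


@dataclass
class ThresholdReport:
    """Where the mask-generation threshold came from."""

    boxes: list[tuple[tuple[int, int, int], tuple[int, int, int]]]  # (origin, shape)
    box_stats: pd.DataFrame        # per-box mean / sd / n
    k: float
    mean: float
    sd: float                      # population SD over pooled voxels
    threshold: float


@dataclass
class TrainingPair:
    """One image patch and its binary spot mask (identical shapes)."""

    image: np.ndarray
    mask: np.ndarray
    source: str = ""
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask patches must share a shape")

    @property
    def positive_fraction(self) -> float:
        return float(self.mask.mean())


def estimate_intensity_threshold(
    vol: IntensityVolume,
    region_boxes: list[tuple[tuple[int, int, int], tuple[int, int, int]]],
    k: float,
) -> ThresholdReport:
    """Threshold = mean + k * SD of intensities pooled over representative boxes.

    Boxes are ``(origin, shape)`` in voxels and must lie inside the volume;
    SD is the population SD of the pooled voxels, so two boxes give exactly
    the single-pass result over their concatenated voxels.
    """
    if not region_boxes:
        raise ValueError("need at least one representative box")
    pooled = []
    stats = []
    for origin, shape in region_boxes:
        origin = tuple(int(o) for o in origin)
        shape = tuple(int(s) for s in shape)
        if any(s < 1 for s in shape):
            raise ValueError(f"empty box of shape {shape}")
        if any(o < 0 or o + s > vol.shape[a] for a, (o, s) in enumerate(zip(origin, shape))):
            raise ValueError(f"box {origin}+{shape} outside volume of shape {vol.shape}")
        box = np.asarray(
            vol.data[tuple(slice(o, o + s) for o, s in zip(origin, shape))], dtype=np.float64
        )
        pooled.append(box.ravel())
        stats.append(
            {"origin": origin, "shape": shape, "n": box.size,
             "mean": float(box.mean()), "sd": float(box.std())}
        )
    voxels = np.concatenate(pooled)
    mean, sd = float(voxels.mean()), float(voxels.std())  # population SD (ddof 0)
    return ThresholdReport(
        boxes=list(region_boxes),
        box_stats=pd.DataFrame(stats),
        k=float(k),
        mean=mean,
        sd=sd,
        threshold=mean + k * sd,
    )


def detect_spots(
    vol: IntensityVolume, threshold: float, min_separation_um: float
) -> np.ndarray:
    """Bright local maxima above ``threshold`` with greedy physical suppression.

    A voxel is a candidate if it equals the maximum of its 26-neighbourhood
    and its intensity is >= threshold.  Candidates are then accepted in
    descending intensity order (ties broken by lexicographic (z, y, x)),
    rejecting any candidate within ``min_separation_um`` (micrometre
    distance, anisotropy-aware) of an already accepted peak.  Returns an
    (n, 3) integer array of voxel coordinates.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_separation_um <= 0:
        raise ValueError("min_separation_um must be > 0")
    data = np.asarray(vol.data, dtype=np.float64)
    local_max = data == ndimage.maximum_filter(data, size=3, mode="nearest")
    cand = np.argwhere(local_max & (data >= threshold))
    if len(cand) == 0:
        return np.zeros((0, 3), dtype=int)
    intens = data[tuple(cand.T)]
    # descending intensity, lexicographic (z, y, x) tie-break
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -intens))
    cand = cand[order]
    vs = np.asarray(vol.voxel_size)
    accepted: list[np.ndarray] = []
    accepted_um: list[np.ndarray] = []
    min_sq = min_separation_um**2
    for c in cand:
        c_um = c * vs
        if all(np.sum((c_um - a) ** 2) >= min_sq for a in accepted_um):
            accepted.append(c)
            accepted_um.append(c_um)
    return np.asarray(accepted, dtype=int)


def render_spot_mask(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    peaks: np.ndarray,
    spot_radius_um: float,
) -> MaskVolume:
    """Union of ellipsoids of physical radius ``spot_radius_um`` at each peak.

    A voxel belongs to a spot when its centre lies within the radius in
    micrometre distance from the peak voxel centre; spots are clipped at the
    volume border and overlaps union idempotently.
    """
    if spot_radius_um <= 0:
        raise ValueError("spot radius must be > 0")
    peaks = np.asarray(peaks, dtype=int).reshape(-1, 3)
    if len(peaks) and (np.any(peaks < 0) or np.any(peaks >= np.asarray(shape))):
        raise ValueError("peaks must lie inside the volume")
    vs = np.asarray(voxel_size)
    half = np.ceil(spot_radius_um / vs).astype(int)
    mask = np.zeros(shape, dtype=np.uint8)
    for p in peaks:
        lo = np.maximum(p - half, 0)
        hi = np.minimum(p + half + 1, shape)
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
        )
        d2 = (
            ((zz - p[0]) * vs[0]) ** 2
            + ((yy - p[1]) * vs[1]) ** 2
            + ((xx - p[2]) * vs[2]) ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= (d2 <= spot_radius_um**2).astype(np.uint8)
    return MaskVolume(mask, tuple(float(v) for v in voxel_size))


def _default_boxes(
    shape: tuple[int, int, int], rng: np.random.Generator, n_boxes: int = 8,
    box_shape: tuple[int, int, int] = (16, 32, 32),
) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    box = tuple(min(b, s) for b, s in zip(box_shape, shape))
    boxes = []
    for _ in range(n_boxes):
        origin = tuple(int(rng.integers(0, s - b + 1)) for s, b in zip(shape, box))
        boxes.append((origin, box))
    return boxes


def build_training_set(
    samples: list,
    config: PipelineConfig,
    patch_shape: tuple[int, int, int] | None = None,
) -> tuple[list[TrainingPair], pd.DataFrame]:
    """Threshold, detect and render per sample, then tile into training patches.

    ``samples`` may mix :class:`~cfosmap.synth.PhantomSample` objects and raw
    signal :class:`IntensityVolume` s.  Returns the patch pairs plus an index
    table with per-patch positive-voxel fractions (the class-balance report).
    A sample with zero detected spots emits patches anyway, with a warning.
    """
    if not samples:
        raise ValueError("need at least one sample")
    patch_shape = tuple(patch_shape) if patch_shape is not None else config.core_shape
    rng = np.random.default_rng(config.seed)
    pairs: list[TrainingPair] = []
    index_rows = []
    for si, sample in enumerate(samples):
        vol = sample.signal if hasattr(sample, "signal") else sample
        report = estimate_intensity_threshold(
            vol, _default_boxes(vol.shape, rng), config.k_thresh
        )
        peaks = detect_spots(vol, report.threshold, config.min_separation_um)
        if len(peaks) == 0:
            warnings.warn(f"sample {si}: no spots detected above threshold {report.threshold:.1f}")
        mask = render_spot_mask(vol.shape, vol.voxel_size, peaks, config.spot_radius_um)
        img_tiles = tile_volume(vol, patch_shape, halo=0)
        mask_tiles = tile_volume(mask, patch_shape, halo=0)
        for (spec_i, img), (_, msk) in zip(img_tiles, mask_tiles):
            pair = TrainingPair(
                image=img.astype(np.float32),
                mask=msk.astype(np.uint8),
                source=f"sample{si}",
                origin=spec_i.core_origin,
            )
            pairs.append(pair)
            index_rows.append(
                {
                    "patch_id": len(pairs) - 1,
                    "source": pair.source,
                    "origin_z": spec_i.core_origin[0],
                    "origin_y": spec_i.core_origin[1],
                    "origin_x": spec_i.core_origin[2],
                    "positive_fraction": pair.positive_fraction,
                    "threshold": report.threshold,
                    "n_spots": len(peaks),
                }
            )
    return pairs, pd.DataFrame(index_rows)
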