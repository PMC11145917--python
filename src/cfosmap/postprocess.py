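"""Whole-volume inference, dual-channel false-positive filters, cell extraction.

Segmentation of a large volume runs patch-wise (reflect-padded halo, cores
stitched back exactly); the resulting signal-channel mask is then cleaned by
three filters, in order:

1. **Autofluorescence filter** — connected components whose overlap fraction
   with the autofluorescence-channel mask reaches a threshold are deleted;
   broadband structures (blood vessels, debris) are bright in both channels,
   real immunostained nuclei only in the signal channel.
2. **No-soma filter** — components outside a physical volume band are
   deleted: too small to contain a soma (noise specks) or too large for a
   single nucleus (vessel fragments, clumps).
3. **Intensity filter** — components whose mean raw intensity is below a
   robust background level (median + k * 1.4826 * MAD over voxels outside
   the mask) are deleted.

Components are 26-connected; each removal is attributed to exactly one
filter (the first that claims it) and the accounting identity
``before - removed = after`` holds exactly.  Surviving components become
cell records with intensity-weighted centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label

from .volume import IntensityVolume, MaskVolume, stitch_masks, tile_volume

__all__ = [
    "FilterReport",
    "segment_volume",
    "autofluorescence_filter",
    "soma_filter",
    "intensity_filter",
    "apply_filter_chain",
    "extract_cells",
]


@dataclass
class FilterReport:
    """Component-level accounting of the three-filter chain."""

    components_before: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    components_after: int = 0
    details: list[dict] = field(default_factory=list)

    def check_identity(self) -> bool:
        return self.components_before - sum(self.removed.values()) == self.components_after

    def to_dict(self) -> dict:
        return {
            "components_before": self.components_before,
            "removed": dict(self.removed),
            "components_after": self.components_after,
            "details": list(self.details),
        }


def segment_volume(model, vol: IntensityVolume, core_shape, halo: int = 0) -> MaskVolume:
    """Patch-wise inference stitched into a full-volume binary mask.

    ``model`` is either a trained network (anything with ``predict_patch``)
    or a plain callable mapping a patch array to a binary array of the same
    shape.  Only the halo-cropped core of each patch prediction is written.
    """
    predict = model.predict_patch if hasattr(model, "predict_patch") else model
    patches = tile_volume(vol, core_shape, halo=halo)
    out = []
    for spec, patch in patches:
        pred = np.asarray(predict(patch)).astype(np.uint8)
        if pred.shape != patch.shape:
            raise ValueError(
                f"predictor returned shape {pred.shape} for patch of shape {patch.shape}"
            )
        out.append((spec, pred))
    return stitch_masks(out, vol.shape, voxel_size=vol.voxel_size)


def _labelled(mask: MaskVolume):
    lab = cc_label(mask.data, connectivity=3)  # 26-connected in 3D
    return lab, int(lab.max())


def _drop(mask_data: np.ndarray, lab: np.ndarray, drop_labels: np.ndarray) -> np.ndarray:
    if drop_labels.size:
        out = mask_data.copy()
        out[np.isin(lab, drop_labels)] = 0
        return out
    return mask_data.copy()


def autofluorescence_filter(
    cfos_mask: MaskVolume, af_mask: MaskVolume, overlap_frac: float = 0.5
) -> tuple[MaskVolume, list[dict]]:
    """Delete signal-channel components co-segmented in the autofluorescence channel.

    A 26-connected component is removed entirely when the fraction of its
    voxels that are also positive in ``af_mask`` is >= ``overlap_frac``.
    """
    if cfos_mask.shape != af_mask.shape:
        raise ValueError(f"shape mismatch: {cfos_mask.shape} vs {af_mask.shape}")
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    lab, n = _labelled(cfos_mask)
    if n == 0:
        return MaskVolume(cfos_mask.data.copy(), cfos_mask.voxel_size), []
    sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    overlap = np.bincount(lab.ravel(), weights=af_mask.data.ravel().astype(float), minlength=n + 1)[1:]
    frac = overlap / sizes
    drop = np.nonzero(frac >= overlap_frac)[0] + 1
    removals = [
        {"component": int(c), "voxel_count": int(sizes[c - 1]),
         "reason": "autofluorescence", "overlap_frac": float(frac[c - 1])}
        for c in drop
    ]
    return MaskVolume(_drop(cfos_mask.data, lab, drop), cfos_mask.voxel_size), removals


def soma_filter(
    mask: MaskVolume, vmin_um3: float = 50.0, vmax_um3: float = 5000.0
) -> tuple[MaskVolume, list[dict]]:
    """Delete components whose physical volume is outside the soma band.

    The band is closed: a component exactly at ``vmin_um3`` or ``vmax_um3``
    is kept.
    """
    if not 0 < vmin_um3 < vmax_um3:
        raise ValueError("need 0 < vmin < vmax")
    lab, n = _labelled(mask)
    if n == 0:
        return MaskVolume(mask.data.copy(), mask.voxel_size), []
    sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    volumes = sizes * mask.voxel_volume_um3
    drop = np.nonzero((volumes < vmin_um3) | (volumes > vmax_um3))[0] + 1
    removals = [
        {"component": int(c), "voxel_count": int(sizes[c - 1]),
         "reason": "no_soma", "volume_um3": float(volumes[c - 1])}
        for c in drop
    ]
    return MaskVolume(_drop(mask.data, lab, drop), mask.voxel_size), removals


def intensity_filter(
    mask: MaskVolume, raw: IntensityVolume, k: float = 3.0
) -> tuple[MaskVolume, list[dict]]:
    """Delete components dimmer than a robust background threshold.

    Background statistics (median and MAD-derived sigma) are computed over
    raw voxels *outside* the mask; a component goes if its mean raw intensity
    is below ``median + k * 1.4826 * MAD``.
    """
    if mask.shape != raw.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {raw.shape}")
    if k < 0:
        raise ValueError("k must be >= 0")
    outside = np.asarray(raw.data)[mask.data == 0]
    if outside.size == 0:
        raise ValueError("mask covers the entire volume; no background to estimate")
    med = float(np.median(outside))
    sigma = 1.4826 * float(np.median(np.abs(outside - med)))
    thresh = med + k * sigma
    lab, n = _labelled(mask)
    if n == 0:
        return MaskVolume(mask.data.copy(), mask.voxel_size), []
    means = ndimage.mean(raw.data, labels=lab, index=np.arange(1, n + 1))
    sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    drop = np.nonzero(means < thresh)[0] + 1
    removals = [
        {"component": int(c), "voxel_count": int(sizes[c - 1]), "reason": "low_intensity",
         "mean_intensity": float(means[c - 1]), "threshold": float(thresh)}
        for c in drop
    ]
    return MaskVolume(_drop(mask.data, lab, drop), mask.voxel_size), removals


def apply_filter_chain(
    cfos_mask: MaskVolume,
    af_mask: MaskVolume,
    raw: IntensityVolume,
    overlap_frac: float = 0.5,
    vmin_um3: float = 50.0,
    vmax_um3: float = 5000.0,
    intensity_k: float = 3.0,
) -> tuple[MaskVolume, FilterReport]:
    """Autofluorescence -> no-soma -> intensity, with exact accounting."""
    report = FilterReport()
    _, report.components_before = _labelled(cfos_mask)
    m, rem_af = autofluorescence_filter(cfos_mask, af_mask, overlap_frac)
    m, rem_soma = soma_filter(m, vmin_um3, vmax_um3)
    m, rem_int = intensity_filter(m, raw, intensity_k)
    report.removed = {
        "autofluorescence": len(rem_af),
        "no_soma": len(rem_soma),
        "low_intensity": len(rem_int),
    }
    report.details = rem_af + rem_soma + rem_int
    _, report.components_after = _labelled(m)
    assert report.check_identity(), "filter accounting identity violated"
    return m, report


def extract_cells(mask: MaskVolume, raw: IntensityVolume) -> pd.DataFrame:
    """Per-cell records from 26-connected components of a filtered mask.

    Centroids are intensity-weighted centres of mass over component voxels
    (in voxel units and micrometres); rows are ordered by centroid (z, y, x)
    and numbered ``cell_id`` from 0 for determinism.
    """
    if mask.shape != raw.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {raw.shape}")
    lab, n = _labelled(mask)
    cols = [
        "cell_id", "z", "y", "x", "z_um", "y_um", "x_um", "voxel_count",
        "volume_um3", "mean_intensity", "max_intensity", "region_id", "hemisphere",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)
    idx = np.arange(1, n + 1)
    raw_data = np.asarray(raw.data, dtype=np.float64)
    com = np.asarray(ndimage.center_of_mass(raw_data, labels=lab, index=idx))
    wsum = ndimage.sum_labels(raw_data, labels=lab, index=idx)
    if np.any(wsum == 0):  # zero-intensity component: geometric centroid fallback
        geo = np.asarray(ndimage.center_of_mass(np.ones_like(raw_data), labels=lab, index=idx))
        com[wsum == 0] = geo[wsum == 0]
    sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    means = ndimage.mean(raw_data, labels=lab, index=idx)
    maxes = ndimage.maximum(raw_data, labels=lab, index=idx)
    vs = np.asarray(mask.voxel_size)
    df = pd.DataFrame(
        {
            "z": com[:, 0],
            "y": com[:, 1],
            "x": com[:, 2],
            "z_um": com[:, 0] * vs[0],
            "y_um": com[:, 1] * vs[1],
            "x_um": com[:, 2] * vs[2],
            "voxel_count": sizes.astype(int),
            "volume_um3": sizes * mask.voxel_volume_um3,
            "mean_intensity": means,
            "max_intensity": maxes,
            "region_id": 0,
            "hemisphere": "unassigned",
        }
    )
    df = df.sort_values(["z", "y", "x"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "cell_id", np.arange(len(df)))
    return df
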