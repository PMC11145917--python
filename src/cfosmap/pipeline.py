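"""Stage orchestration over a fixed workspace layout.

A workspace directory accumulates the pipeline's artifacts in conventional
subdirectories::

    raw/      signal.tif, autofluorescence.tif, truth_cells.csv, vessel_mask.tif
    atlas/    annotation.tif, ontology.json, transform.json
    counts/   group_counts.csv              (simulated cohort table)
    train/    patches.npz, index.csv
    model/    checkpoint.npz, metrics.csv
    masks/    signal_mask.tif, autofluorescence_mask.tif
    cells/    cells.csv, filtered_mask.tif, filter_report.json
    quant/    cells_mapped.csv, counts_level<L>.csv, hemisphere_level<L>.csv
    stats/    region_stats.csv, correlation_<group>.csv
    reports/  <stage>.json                  (hashes + timing per stage)

Stages run in the order ``simulate, make-masks, train, predict, postprocess,
quantify, stats``; each checks that its prerequisite artifacts exist and
names the missing file otherwise.  With fixed seeds in the config the
deterministic stages are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import tifffile

from . import atlas as atlas_mod
from . import postprocess as pp
from . import stats as gstats
from .config import PipelineConfig
from .nn import build_model, load_checkpoint, save_checkpoint, train_model
from .synth import GroupDesign, PhantomSpec, generate_group_counts, generate_phantom, generate_toy_atlas
from .trainmask import TrainingPair, build_training_set
from .volume import IntensityVolume, read_volume

log = logging.getLogger("cfosmap")

STAGES = ("simulate", "make-masks", "train", "predict", "postprocess", "quantify", "stats")

__all__ = ["STAGES", "run_stage", "run_all"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_current_inputs: list[str] = []  # prerequisite paths recorded for the stage report


def _require(workspace: str, *relpaths: str) -> list[str]:
    out = []
    for rel in relpaths:
        path = os.path.join(workspace, rel)
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing prerequisite artifact: {path}")
        out.append(path)
        _current_inputs.append(rel)
    return out


def _stage_simulate(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    spec = overrides.get("phantom_spec") or PhantomSpec(seed=cfg.seed)
    sample = generate_phantom(spec)
    sample.write(os.path.join(ws, "raw"))
    atlas = generate_toy_atlas(
        shape=sample.signal.shape,
        n_superregions=overrides.get("n_superregions", 2),
        n_children_per=overrides.get("n_children_per", 2),
        voxel_size=sample.signal.voxel_size,
        seed=cfg.seed,
    )
    os.makedirs(os.path.join(ws, "atlas"), exist_ok=True)
    atlas.save(os.path.join(ws, "atlas", "annotation.tif"), os.path.join(ws, "atlas", "ontology.json"))
    # image micrometres -> atlas voxels: the toy atlas shares the phantom grid
    transform = atlas_mod.AffineTransform.scaling([1.0 / v for v in sample.signal.voxel_size])
    transform.to_json(os.path.join(ws, "atlas", "transform.json"))
    design = overrides.get("group_design") or GroupDesign.planted(seed=cfg.seed)
    counts = generate_group_counts(design)
    os.makedirs(os.path.join(ws, "counts"), exist_ok=True)
    counts.to_csv(os.path.join(ws, "counts", "group_counts.csv"), index=False)
    return [
        "raw/signal.tif", "raw/autofluorescence.tif", "raw/truth_cells.csv",
        "raw/vessel_mask.tif", "atlas/annotation.tif", "atlas/ontology.json",
        "atlas/transform.json", "counts/group_counts.csv",
    ]


def _stage_make_masks(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    (signal_path,) = _require(ws, "raw/signal.tif")
    vol = read_volume(signal_path, channel="signal", voxel_size=cfg.voxel_size)
    pairs, index = build_training_set([vol], cfg, patch_shape=cfg.core_shape)
    os.makedirs(os.path.join(ws, "train"), exist_ok=True)
    np.savez_compressed(
        os.path.join(ws, "train", "patches.npz"),
        images=np.stack([p.image for p in pairs]),
        masks=np.stack([p.mask for p in pairs]),
    )
    index.to_csv(os.path.join(ws, "train", "index.csv"), index=False)
    return ["train/patches.npz", "train/index.csv"]


def _stage_train(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    (patches_path,) = _require(ws, "train/patches.npz")
    with np.load(patches_path) as archive:
        pairs = [
            TrainingPair(image=img, mask=msk)
            for img, msk in zip(archive["images"], archive["masks"])
        ]
    model = build_model(cfg.model)
    report = train_model(
        model,
        pairs,
        epochs=overrides.get("epochs", 4),
        lr=overrides.get("lr", 3e-4),
        batch_size=overrides.get("batch_size", 8),
        seed=cfg.seed,
    )
    os.makedirs(os.path.join(ws, "model"), exist_ok=True)
    save_checkpoint(model, os.path.join(ws, "model", "checkpoint.npz"))
    pd.DataFrame(
        {"epoch": np.arange(1, len(report.epoch_loss) + 1),
         "loss": report.epoch_loss, "val_dice": report.val_dice}
    ).to_csv(os.path.join(ws, "model", "metrics.csv"), index=False)
    return ["model/checkpoint.npz", "model/metrics.csv"]


def _stage_predict(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    ckpt = os.path.join(ws, "model", "checkpoint.npz")
    if not os.path.exists(ckpt):
        raise FileNotFoundError(f"model checkpoint not found: {ckpt}")
    _require(ws, "raw/signal.tif", "raw/autofluorescence.tif")
    model = load_checkpoint(ckpt)
    os.makedirs(os.path.join(ws, "masks"), exist_ok=True)
    outputs = []
    for channel, fname in (("signal", "signal.tif"), ("autofluorescence", "autofluorescence.tif")):
        vol = read_volume(os.path.join(ws, "raw", fname), channel=channel, voxel_size=cfg.voxel_size)
        mask = pp.segment_volume(model, vol, cfg.core_shape, halo=cfg.halo)
        out = f"masks/{channel}_mask.tif"
        tifffile.imwrite(os.path.join(ws, out), mask.data)
        outputs.append(out)
    return outputs


def _stage_postprocess(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    _require(ws, "masks/signal_mask.tif", "masks/autofluorescence_mask.tif", "raw/signal.tif")
    from .volume import MaskVolume

    raw = read_volume(os.path.join(ws, "raw", "signal.tif"), voxel_size=cfg.voxel_size)
    cfos = MaskVolume(tifffile.imread(os.path.join(ws, "masks", "signal_mask.tif")), cfg.voxel_size)
    af = MaskVolume(tifffile.imread(os.path.join(ws, "masks", "autofluorescence_mask.tif")), cfg.voxel_size)
    filtered, report = pp.apply_filter_chain(
        cfos, af, raw,
        overlap_frac=cfg.af_overlap_frac,
        vmin_um3=cfg.soma_volume_um3_min,
        vmax_um3=cfg.soma_volume_um3_max,
        intensity_k=cfg.intensity_k,
    )
    cells = pp.extract_cells(filtered, raw)
    os.makedirs(os.path.join(ws, "cells"), exist_ok=True)
    tifffile.imwrite(os.path.join(ws, "cells", "filtered_mask.tif"), filtered.data)
    cells.to_csv(os.path.join(ws, "cells", "cells.csv"), index=False)
    with open(os.path.join(ws, "cells", "filter_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    return ["cells/filtered_mask.tif", "cells/cells.csv", "cells/filter_report.json"]


def _stage_quantify(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    _require(ws, "cells/cells.csv", "atlas/annotation.tif", "atlas/ontology.json", "atlas/transform.json")
    cells = pd.read_csv(os.path.join(ws, "cells", "cells.csv"))
    atlas = atlas_mod.AtlasBundle.load(
        os.path.join(ws, "atlas", "annotation.tif"),
        os.path.join(ws, "atlas", "ontology.json"),
        voxel_size=cfg.voxel_size,
    )
    transform = atlas_mod.AffineTransform.from_json(os.path.join(ws, "atlas", "transform.json"))
    mapped = atlas_mod.map_cells_to_atlas(cells, transform, atlas)
    os.makedirs(os.path.join(ws, "quant"), exist_ok=True)
    mapped.to_csv(os.path.join(ws, "quant", "cells_mapped.csv"), index=False)
    outputs = ["quant/cells_mapped.csv"]
    deepest = max(atlas.ontology.levels)
    for level in atlas.ontology.levels[1:]:  # skip the root level
        table = atlas_mod.counts_by_level(mapped, atlas, level)
        rel = f"quant/counts_level{level}.csv"
        table.to_csv(os.path.join(ws, rel), index=False)
        outputs.append(rel)
    hemi = atlas_mod.hemisphere_counts(mapped, atlas, deepest)
    rel = f"quant/hemisphere_level{deepest}.csv"
    hemi.to_csv(os.path.join(ws, rel), index=False)
    outputs.append(rel)
    return outputs


def _stage_stats(cfg: PipelineConfig, ws: str, overrides: dict) -> list[str]:
    (counts_path,) = _require(ws, "counts/group_counts.csv")
    counts = pd.read_csv(counts_path)
    groups = list(dict.fromkeys(counts["group"]))
    if len(groups) < 2:
        raise ValueError("group statistics need at least two groups")
    pair = overrides.get("compare", (groups[-1], groups[0]))  # default: treatment vs first/control
    table = gstats.compare_groups(
        counts, pair[0], pair[1], fc_cut=cfg.fc_cut, q_cut=cfg.q_cut
    )
    os.makedirs(os.path.join(ws, "stats"), exist_ok=True)
    table.to_csv(os.path.join(ws, "stats", "region_stats.csv"), index=False)
    outputs = ["stats/region_stats.csv"]
    for group in groups:
        mat = gstats.counts_matrix(counts, group)
        if len(mat) >= 3:
            cmap = gstats.correlation_map(mat)
            rel = f"stats/correlation_{group}.csv"
            cmap.rho.to_csv(os.path.join(ws, rel))
            outputs.append(rel)
    return outputs


_RUNNERS = {
    "simulate": _stage_simulate,
    "make-masks": _stage_make_masks,
    "train": _stage_train,
    "predict": _stage_predict,
    "postprocess": _stage_postprocess,
    "quantify": _stage_quantify,
    "stats": _stage_stats,
}


def run_stage(stage: str, config: PipelineConfig, workspace: str | os.PathLike, **overrides) -> dict:
    """Run one pipeline stage in a workspace and write its JSON report."""
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    ws = os.fspath(workspace)
    os.makedirs(ws, exist_ok=True)
    log.info("stage %s starting in %s", stage, ws)
    _current_inputs.clear()
    t0 = time.perf_counter()
    outputs = _RUNNERS[stage](config, ws, overrides)
    elapsed = time.perf_counter() - t0
    report = {
        "stage": stage,
        "elapsed_s": elapsed,
        "seed": config.seed,
        "inputs": {rel: _sha256(os.path.join(ws, rel)) for rel in _current_inputs},
        "outputs": {rel: _sha256(os.path.join(ws, rel)) for rel in outputs},
    }
    os.makedirs(os.path.join(ws, "reports"), exist_ok=True)
    with open(os.path.join(ws, "reports", f"{stage}.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    log.info("stage %s done in %.1fs", stage, elapsed)
    return report


def run_all(config: PipelineConfig, workspace: str | os.PathLike, **overrides) -> list[dict]:
    """Run the seven stages in order; returns their reports."""
    return [run_stage(stage, config, workspace, **overrides) for stage in STAGES]
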