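"""Atlas-space quantification of segmented cells.

An :class:`AtlasBundle` pairs an integer annotation volume (label 0 = outside
the brain) with a rooted hierarchical ontology in the Allen structure-graph
style (``id``, ``acronym``, ``name``, ``parent_structure_id``, plus explicit
``level`` and optional cortical ``layer`` tags).  Cells are mapped into atlas
space by an affine transform from image micrometre coordinates to atlas voxel
indices — registration itself is an input to this package, not a computation
— and then aggregated into per-region counts at any ontology level, per
hemisphere, per cortical layer, and along the anterior-posterior axis.

All aggregations satisfy exact conservation: counts at any level plus the
unassigned remainder equal the total number of cells, hemisphere counts sum
to bilateral counts, layer counts sum to their parent's count, and AP-bin
counts sum to the region count.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OntologyNode",
    "Ontology",
    "AtlasBundle",
    "AffineTransform",
    "map_cells_to_atlas",
    "counts_by_level",
    "layer_metrics",
    "hemisphere_counts",
    "ap_profile",
]


@dataclass(frozen=True)
class OntologyNode:
    id: int
    acronym: str
    name: str
    parent_id: int | None
    level: int
    layer: str | None = None


class Ontology:
    """A single rooted region tree with levels increasing from root to leaves."""

    def __init__(self, nodes: list[OntologyNode]):
        self.nodes: dict[int, OntologyNode] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate node ids in ontology")
        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise ValueError(f"node {n.id} has unknown parent {n.parent_id}")
                if self.nodes[n.parent_id].level >= n.level:
                    raise ValueError(f"level must increase from parent to child at node {n.id}")
                self._children[n.parent_id].append(n.id)
        # reject cycles / disconnected parts: every node must reach the root
        for n in nodes:
            self.ancestors(n.id)

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def ancestors(self, node_id: int) -> list[int]:
        """Path root -> ... -> node (inclusive)."""
        path = [node_id]
        seen = {node_id}
        while self.nodes[path[-1]].parent_id is not None:
            p = self.nodes[path[-1]].parent_id
            if p in seen:
                raise ValueError(f"cycle in ontology at node {node_id}")
            path.append(p)
            seen.add(p)
        return path[::-1]

    def ancestor_at_level(self, node_id: int, level: int) -> int | None:
        """The node's ancestor (or itself) at ``level``; None if node is shallower."""
        for a in self.ancestors(node_id):
            if self.nodes[a].level == level:
                return a
        return None

    def descendants(self, node_id: int) -> list[int]:
        out = [node_id]
        stack = [node_id]
        while stack:
            for c in self._children[stack.pop()]:
                out.append(c)
                stack.append(c)
        return out

    def leaves(self, under: int | None = None) -> list[int]:
        pool = self.descendants(under) if under is not None else list(self.nodes)
        return [i for i in pool if not self._children[i]]

    def nodes_at_level(self, level: int) -> list[int]:
        return [i for i, n in self.nodes.items() if n.level == level]

    @property
    def levels(self) -> list[int]:
        return sorted({n.level for n in self.nodes.values()})

    def to_json(self, path: str | os.PathLike) -> None:
        doc = [
            {
                "id": n.id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_structure_id": n.parent_id,
                "level": n.level,
                "layer": n.layer,
            }
            for n in self.nodes.values()
        ]
        with open(os.fspath(path), "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "Ontology":
        with open(os.fspath(path)) as fh:
            doc = json.load(fh)
        nodes = [
            OntologyNode(
                id=int(d["id"]),
                acronym=d["acronym"],
                name=d.get("name", d["acronym"]),
                parent_id=None if d["parent_structure_id"] is None else int(d["parent_structure_id"]),
                level=int(d["level"]),
                layer=d.get("layer"),
            )
            for d in doc
        ]
        return cls(nodes)


@dataclass
class AtlasBundle:
    """Annotation volume + ontology + geometry needed for quantification."""

    annotation: np.ndarray              # integer labels, 0 = outside brain
    ontology: Ontology
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)  # um
    midline_axis: int = 2               # mediolateral axis (x)
    midline_index: int | None = None    # default: middle of that axis
    ap_axis: int = 0                    # anterior->posterior axis (z planes)

    def __post_init__(self) -> None:
        self.annotation = np.asarray(self.annotation)
        if self.annotation.ndim != 3:
            raise ValueError("annotation must be 3D")
        if self.midline_index is None:
            self.midline_index = self.annotation.shape[self.midline_axis] // 2
        labels = set(np.unique(self.annotation)) - {0}
        unknown = labels - set(self.ontology.nodes)
        if unknown:
            raise ValueError(f"annotation labels missing from ontology: {sorted(unknown)[:5]}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx * 1e-9

    def region_voxel_counts(self) -> dict[int, int]:
        """Voxels carrying each annotation label (labels only, no roll-up)."""
        flat = self.annotation.ravel()
        counts = np.bincount(flat)
        return {int(i): int(c) for i, c in enumerate(counts) if c > 0 and i != 0}

    def subtree_voxel_count(self, node_id: int) -> int:
        per_label = self.region_voxel_counts()
        return sum(per_label.get(d, 0) for d in self.ontology.descendants(node_id))

    def save(self, annotation_path, ontology_path) -> None:
        tifffile.imwrite(os.fspath(annotation_path), self.annotation.astype(np.uint32))
        self.ontology.to_json(ontology_path)

    @classmethod
    def load(cls, annotation_path, ontology_path, **kwargs) -> "AtlasBundle":
        return cls(
            annotation=tifffile.imread(os.fspath(annotation_path)),
            ontology=Ontology.from_json(ontology_path),
            **kwargs,
        )


@dataclass
class AffineTransform:
    """4x4 homogeneous map from image (z, y, x) micrometres to atlas voxel indices."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform must be a 4x4 matrix")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row of an affine transform must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("singular transform")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def scaling(cls, factors) -> "AffineTransform":
        m = np.eye(4)
        m[0, 0], m[1, 1], m[2, 2] = factors
        return cls(m)

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        with open(os.fspath(path)) as fh:
            return cls(np.asarray(json.load(fh)["matrix"], dtype=float))

    def to_json(self, path) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump({"matrix": self.matrix.tolist()}, fh)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        return (hom @ self.matrix.T)[:, :3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


def map_cells_to_atlas(cells: pd.DataFrame, transform: AffineTransform, atlas: AtlasBundle) -> pd.DataFrame:
    """Assign each cell an atlas region id and a hemisphere.

    Centroids in image micrometres (columns ``z_um, y_um, x_um``) are pushed
    through the affine, rounded to the nearest atlas voxel and looked up in
    the annotation (0 when outside the annotation box or outside the brain).
    Hemisphere is split at the atlas midline: voxel index below the midline
    is "L", at or above is "R".
    """
    out = cells.copy()
    if len(out) == 0:
        out["region_id"] = pd.Series(dtype=int)
        out["hemisphere"] = pd.Series(dtype=object)
        return out
    pts = out[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    vox = np.rint(transform.apply(pts)).astype(int)
    shape = atlas.annotation.shape
    inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    region = np.zeros(len(out), dtype=int)
    region[inside] = atlas.annotation[tuple(vox[inside].T)]
    out["region_id"] = region
    hemi = np.where(vox[:, atlas.midline_axis] < atlas.midline_index, "L", "R")
    hemi = np.where(inside, hemi, "unassigned")
    out["hemisphere"] = hemi
    out[["atlas_z", "atlas_y", "atlas_x"]] = vox
    return out


def _require_known_regions(cells: pd.DataFrame, atlas: AtlasBundle) -> None:
    ids = set(cells["region_id"].unique()) - {0}
    unknown = ids - set(atlas.ontology.nodes)
    if unknown:
        raise ValueError(f"unknown region ids in cell table: {sorted(unknown)[:5]}")


def _level_of(cells: pd.DataFrame, atlas: AtlasBundle, level: int) -> pd.Series:
    """Each cell's ancestor region at ``level`` (0 = unassigned at that level)."""
    ont = atlas.ontology
    lut = {0: 0}
    for rid in cells["region_id"].unique():
        if rid != 0:
            anc = ont.ancestor_at_level(int(rid), level)
            lut[int(rid)] = 0 if anc is None else anc
    return cells["region_id"].map(lut)


def counts_by_level(cells: pd.DataFrame, atlas: AtlasBundle, level: int) -> pd.DataFrame:
    """Per-region cell counts at one ontology level (per animal if labelled).

    Every region at the level appears, including zero-count ones; region
    volume is the voxel volume of the region's full subtree, and density is
    count per mm^3.
    """
    if level not in atlas.ontology.levels:
        raise ValueError(f"level {level} not present in ontology (levels: {atlas.ontology.levels})")
    _require_known_regions(cells, atlas)
    regions = sorted(atlas.ontology.nodes_at_level(level))
    vol_mm3 = {r: atlas.subtree_voxel_count(r) * atlas.voxel_volume_mm3 for r in regions}

    animals = sorted(cells["animal"].unique()) if "animal" in cells.columns and len(cells) else [None]
    group_of = (
        cells.drop_duplicates("animal").set_index("animal")["group"].to_dict()
        if "group" in cells.columns and "animal" in cells.columns
        else {}
    )
    at_level = _level_of(cells, atlas, level) if len(cells) else pd.Series(dtype=int)
    rows = []
    for animal in animals:
        sel = cells["animal"] == animal if animal is not None else np.ones(len(cells), dtype=bool)
        tallies = at_level[np.asarray(sel)].value_counts() if len(cells) else pd.Series(dtype=int)
        for r in regions:
            count = int(tallies.get(r, 0))
            v = vol_mm3[r]
            rows.append(
                {
                    "animal": animal,
                    "group": group_of.get(animal),
                    "region_id": r,
                    "acronym": atlas.ontology.nodes[r].acronym,
                    "level": level,
                    "count": count,
                    "region_volume_mm3": v,
                    "density_per_mm3": count / v if v > 0 else np.nan,
                }
            )
        rows.append(
            {
                "animal": animal,
                "group": group_of.get(animal),
                "region_id": 0,
                "acronym": "unassigned",
                "level": level,
                "count": int((tallies.get(0, 0))) if len(cells) else 0,
                "region_volume_mm3": np.nan,
                "density_per_mm3": np.nan,
            }
        )
    return pd.DataFrame(rows)


def layer_metrics(
    cells: pd.DataFrame,
    mask,
    atlas: AtlasBundle,
    parent_region: int,
) -> pd.DataFrame:
    """Per-cortical-layer count, density and volume ratio under one region.

    ``mask`` is a binary segmentation volume aligned to the atlas annotation
    grid; volume ratio is the fraction of each layer's voxels that are
    mask-positive (the fraction of the layer occupied by segmented signal).
    """
    ont = atlas.ontology
    layer_nodes = [d for d in ont.descendants(parent_region) if ont.nodes[d].layer is not None]
    if not layer_nodes:
        raise ValueError(f"region {parent_region} has no layer-tagged descendants")
    mask_data = np.asarray(mask.data if hasattr(mask, "data") else mask).astype(bool)
    if mask_data.shape != atlas.annotation.shape:
        raise ValueError("mask must be aligned to the atlas annotation grid")
    _require_known_regions(cells, atlas)
    cell_regions = cells["region_id"].to_numpy() if len(cells) else np.array([], dtype=int)
    by_layer: dict[str, dict] = {}
    for node in sorted(layer_nodes):
        tag = ont.nodes[node].layer
        labels = ont.descendants(node)
        in_layer = np.isin(atlas.annotation, labels)
        layer_vox = int(in_layer.sum())
        vol = layer_vox * atlas.voxel_volume_mm3
        count = int(np.isin(cell_regions, labels).sum())
        rec = by_layer.setdefault(
            tag, {"layer": tag, "count": 0, "layer_volume_mm3": 0.0, "_pos": 0, "_vox": 0}
        )
        rec["count"] += count
        rec["layer_volume_mm3"] += vol
        rec["_pos"] += int(mask_data[in_layer].sum())
        rec["_vox"] += layer_vox
    rows = []
    for tag in sorted(by_layer):
        rec = by_layer[tag]
        vol = rec["layer_volume_mm3"]
        rows.append(
            {
                "layer": tag,
                "count": rec["count"],
                "density_per_mm3": rec["count"] / vol if vol > 0 else np.nan,
                "volume_ratio": rec["_pos"] / rec["_vox"] if rec["_vox"] > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def hemisphere_counts(cells: pd.DataFrame, atlas: AtlasBundle, level: int) -> pd.DataFrame:
    """Left/right per-region counts at one level; L + R = bilateral count."""
    _require_known_regions(cells, atlas)
    regions = sorted(atlas.ontology.nodes_at_level(level))
    at_level = _level_of(cells, atlas, level) if len(cells) else pd.Series(dtype=int)
    rows = []
    for r in regions:
        sel = np.asarray(at_level == r) if len(cells) else np.array([], dtype=bool)
        hemi = cells.loc[sel, "hemisphere"] if len(cells) else pd.Series(dtype=object)
        left = int((hemi == "L").sum())
        right = int((hemi == "R").sum())
        rows.append(
            {
                "region_id": r,
                "acronym": atlas.ontology.nodes[r].acronym,
                "level": level,
                "count_L": left,
                "count_R": right,
                "count_bilateral": left + right,
            }
        )
    return pd.DataFrame(rows)


def ap_profile(cells: pd.DataFrame, atlas: AtlasBundle, region: int, n_bins: int) -> pd.DataFrame:
    """Anterior-posterior distribution of a region's cells in equal bins.

    The region's AP extent is the min..max annotated voxel of its subtree on
    the AP axis, split into ``n_bins`` equal half-open bins (last bin closed).
    Cells are binned by their atlas AP coordinate; per-animal rows when the
    table is labelled.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _require_known_regions(cells, atlas)
    ont = atlas.ontology
    labels = ont.descendants(region)
    where = np.nonzero(np.isin(atlas.annotation, labels))
    if where[0].size == 0:
        raise ValueError(f"region {region} has no annotated voxels")
    ap = where[atlas.ap_axis]
    lo, hi = float(ap.min()), float(ap.max()) + 1.0  # voxel extents, half-open overall
    edges = np.linspace(lo, hi, n_bins + 1)

    in_region = np.isin(cells["region_id"].to_numpy(), labels) if len(cells) else np.array([], dtype=bool)
    sub = cells.loc[in_region].copy()
    ap_col = {0: "atlas_z", 1: "atlas_y", 2: "atlas_x"}[atlas.ap_axis]
    if ap_col not in sub.columns:
        raise ValueError("cells must be mapped to atlas space first (map_cells_to_atlas)")
    coord = sub[ap_col].to_numpy(dtype=float) if len(sub) else np.array([])
    # half-open [a, b) bins, last closed: clamp the top edge inward
    idx = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, n_bins - 1) if len(sub) else np.array([], dtype=int)
    sub["ap_bin"] = idx
    animals = sorted(sub["animal"].unique()) if "animal" in sub.columns and len(sub) else [None]
    rows = []
    for animal in animals:
        s = sub if animal is None else sub[sub["animal"] == animal]
        tallies = s["ap_bin"].value_counts()
        for b in range(n_bins):
            rows.append(
                {
                    "animal": animal,
                    "region_id": region,
                    "ap_bin": b,
                    "ap_lo_voxel": edges[b],
                    "ap_hi_voxel": edges[b + 1],
                    "count": int(tallies.get(b, 0)),
                }
            )
    return pd.DataFrame(rows)
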