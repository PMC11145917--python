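"""Synthetic phantoms, toy atlases and group count tables with exact ground truth.

The generator emulates the study conditions of dual-channel light-sheet
imaging of immunostained brains at desk scale:

* **Cells** — sparse, soma-scale bright spots rendered as Gaussians that are
  isotropic in micrometres (sigma = radius / 2) on an anisotropic voxel grid
  (default 1 x 1 x 3.5 um), present only in the signal (c-Fos) channel.
* **Vessels** — smoothed random-walk tubes visible in *both* channels: full
  intensity in the autofluorescence channel and a bleed-through fraction in
  the signal channel.  These are the dominant false-positive class the
  dual-channel post-processing filters exist to remove.
* **Noise** — constant background plus Gaussian read noise (added last).

Ground truth (cell centroids/radii/peaks and the vessel mask) is returned
exactly; cells are placed with a margin of at least one radius from the
border and a minimum mutual separation so each renders as a distinct local
maximum in the noise-free image.

The toy atlas is a nested rectangular partition with a 3-level ontology
(root -> superregions -> leaves), optionally split into L1..L6 layer slabs,
mirroring the hierarchical structure of a reference brain atlas.  Group count
tables are lognormal around per-region baselines with planted multiplicative
group effects, the statistical stand-in for per-region cell counts of a
cohort experiment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasBundle, Ontology, OntologyNode
from .volume import IntensityVolume, MaskVolume

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_toy_atlas",
    "GroupDesign",
    "generate_group_counts",
]


@dataclass
class PhantomSpec:
    """Parameters of one dual-channel phantom volume."""

    shape: tuple[int, int, int] = (64, 160, 160)
    voxel_size: tuple[float, float, float] = (3.5, 1.0, 1.0)
    n_cells: int = 200
    cell_radius_um: tuple[float, float] = (2.5, 4.0)
    cell_peak_intensity: tuple[float, float] = (800.0, 2000.0)
    background_level: float = 100.0
    noise_sd: float = 10.0
    n_vessels: int = 10
    vessel_radius_um: float = 4.0
    vessel_intensity: float = 1500.0
    autofl_bleed_frac: float = 0.6
    min_separation_factor: float = 4.0  # centroid separation >= factor * max radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_vessels < 0:
            raise ValueError("counts must be >= 0")
        if min(self.cell_radius_um) <= 0 or self.vessel_radius_um <= 0:
            raise ValueError("radii must be > 0")
        if not 0.0 <= self.autofl_bleed_frac <= 1.0:
            raise ValueError("autofl_bleed_frac must be in [0, 1]")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background and noise must be >= 0")


@dataclass
class PhantomSample:
    """A rendered phantom plus its exact ground truth."""

    signal: IntensityVolume
    autofl: IntensityVolume
    truth_cells: pd.DataFrame        # columns z_um, y_um, x_um, radius_um, peak
    truth_vessel_mask: MaskVolume
    spec: PhantomSpec

    def write(self, directory: str | os.PathLike) -> None:
        from .volume import write_volume

        d = os.fspath(directory)
        os.makedirs(d, exist_ok=True)
        import tifffile

        # intensities quantised to uint16 on disk, like raw camera counts
        for vol, name in ((self.signal, "signal.tif"), (self.autofl, "autofluorescence.tif")):
            tifffile.imwrite(
                os.path.join(d, name),
                np.clip(np.rint(vol.data), 0, 65535).astype(np.uint16),
            )
        write_volume(self.truth_vessel_mask, os.path.join(d, "vessel_mask.tif"))
        self.truth_cells.to_csv(os.path.join(d, "truth_cells.csv"), index=False)


def _place_cells(
    spec: PhantomSpec, rng: np.random.Generator, vessel_dist_um: np.ndarray | None = None
) -> pd.DataFrame:
    """Rejection-sample centroids (um) with border margin and mutual separation.

    ``vessel_dist_um`` (physical distance transform of the vessel mask) keeps
    somata out of and away from vessels, so each planted cell is a separate
    object from the vessel network.
    """
    extent = np.asarray(spec.shape, dtype=float) * np.asarray(spec.voxel_size)
    vs = np.asarray(spec.voxel_size)
    r_lo, r_hi = spec.cell_radius_um
    min_sep = spec.min_separation_factor * r_hi
    placed: list[np.ndarray] = []
    radii: list[float] = []
    max_tries = 200 * max(spec.n_cells, 1)
    tries = 0
    while len(placed) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with separation {min_sep:.1f} um "
                f"in a {tuple(extent)} um volume"
            )
        r = rng.uniform(r_lo, r_hi)
        margin = 3.0 * r  # keep the rendered spot (3 sigma ~ 1.5 r, plus slack) off the border
        if np.any(extent - 2 * margin <= 0):
            raise RuntimeError("volume too small for the requested cell radius")
        pos = rng.uniform(margin, extent - margin)
        if vessel_dist_um is not None:
            vox = np.minimum(np.floor(pos / vs).astype(int), np.asarray(spec.shape) - 1)
            if vessel_dist_um[tuple(vox)] < 3.0 * r + 2.0:
                continue
        if all(np.linalg.norm(pos - q) >= min_sep for q in placed):
            placed.append(pos)
            radii.append(r)
    peaks = rng.uniform(*spec.cell_peak_intensity, size=len(placed))
    arr = np.asarray(placed) if placed else np.zeros((0, 3))
    return pd.DataFrame(
        {
            "z_um": arr[:, 0] if len(placed) else [],
            "y_um": arr[:, 1] if len(placed) else [],
            "x_um": arr[:, 2] if len(placed) else [],
            "radius_um": radii,
            "peak": peaks if len(placed) else [],
        }
    )


def _render_cells(canvas: np.ndarray, cells: pd.DataFrame, voxel_size) -> None:
    vs = np.asarray(voxel_size)
    for _, cell in cells.iterrows():
        center = np.array([cell.z_um, cell.y_um, cell.x_um])
        sigma = cell.radius_um / 2.0
        half = np.ceil(4 * sigma / vs).astype(int)  # 4-sigma support box
        c_vox = center / vs
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, canvas.shape)
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[a], hi[a]) * vs[a] for a in range(3)), indexing="ij"
        )
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += cell.peak * np.exp(-d2 / (2 * sigma**2))


def _render_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-walk tubes as a boolean mask; walks wander inside the volume."""
    extent = np.asarray(spec.shape, dtype=float) * np.asarray(spec.voxel_size)
    vs = np.asarray(spec.voxel_size)
    mask = np.zeros(spec.shape, dtype=bool)
    step = max(spec.vessel_radius_um / 2.0, 1.0)
    n_steps = int(0.6 * extent.max() / step)
    r_vox = np.ceil(spec.vessel_radius_um / vs).astype(int)
    for _ in range(spec.n_vessels):
        pos = rng.uniform(0.1 * extent, 0.9 * extent)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(n_steps):
            direction = direction + 0.35 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + step * direction
            pos = np.clip(pos, 0.0, extent - vs)  # stay inside; clipping bends the walk
            c_vox = pos / vs
            lo = np.maximum(np.floor(c_vox).astype(int) - r_vox, 0)
            hi = np.minimum(np.floor(c_vox).astype(int) + r_vox + 1, spec.shape)
            zz, yy, xx = np.meshgrid(
                *(np.arange(lo[a], hi[a]) * vs[a] for a in range(3)), indexing="ij"
            )
            d2 = (zz - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (xx - pos[2]) ** 2
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= spec.vessel_radius_um**2
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a dual-channel phantom with exact ground truth.

    Cells appear in the signal channel only; vessels appear in both channels
    (signal at ``autofl_bleed_frac`` of the vessel intensity); Gaussian noise
    is added last.  Identical specs (including seed) give identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    vessel_mask = _render_vessels(spec, rng)
    if vessel_mask.any() and spec.n_cells:
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~vessel_mask, sampling=spec.voxel_size)
    else:
        dist = None
    cells = _place_cells(spec, rng, vessel_dist_um=dist)

    signal = np.full(spec.shape, float(spec.background_level), dtype=np.float64)
    autofl = np.full(spec.shape, float(spec.background_level), dtype=np.float64)
    _render_cells(signal, cells, spec.voxel_size)
    autofl[vessel_mask] += spec.vessel_intensity
    signal[vessel_mask] += spec.autofl_bleed_frac * spec.vessel_intensity
    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=spec.shape)
        autofl += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    signal = np.clip(signal, 0, None).astype(np.float32)
    autofl = np.clip(autofl, 0, None).astype(np.float32)
    return PhantomSample(
        signal=IntensityVolume(signal, spec.voxel_size, "signal"),
        autofl=IntensityVolume(autofl, spec.voxel_size, "autofluorescence"),
        truth_cells=cells,
        truth_vessel_mask=MaskVolume(vessel_mask.astype(np.uint8), spec.voxel_size),
        spec=spec,
    )


def generate_toy_atlas(
    shape: tuple[int, int, int] = (64, 64, 64),
    n_superregions: int = 2,
    n_children_per: int = 2,
    with_layers: bool = False,
    n_layers: int = 6,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0),
) -> AtlasBundle:
    """Build a nested rectangular toy atlas with a root/superregion/leaf tree.

    The brain box (everything except a one-voxel zero border) is split along
    z into superregions and each superregion along y into leaves.  With
    ``with_layers`` each leaf is further split along x into ``n_layers``
    slabs tagged "L1".."L6"; the annotation then carries the layer-node ids
    (the deepest level).  The midline is the middle index of the x axis.
    """
    shape = tuple(int(s) for s in shape)
    inner = tuple(s - 2 for s in shape)
    if n_superregions < 1 or n_children_per < 1 or (with_layers and n_layers < 2):
        raise ValueError("invalid partition request")
    if inner[0] < n_superregions or inner[1] < n_children_per or (with_layers and inner[2] < n_layers):
        raise ValueError(f"shape {shape} too small for the requested partition")

    nodes = [OntologyNode(id=1, acronym="root", name="root", parent_id=None, level=1)]
    annotation = np.zeros(shape, dtype=np.uint32)
    z_edges = np.linspace(1, shape[0] - 1, n_superregions + 1).astype(int)
    y_edges = np.linspace(1, shape[1] - 1, n_children_per + 1).astype(int)
    x_edges = np.linspace(1, shape[2] - 1, (n_layers if with_layers else 1) + 1).astype(int)

    next_id = 2
    for si in range(n_superregions):
        super_id = next_id
        next_id += 1
        nodes.append(
            OntologyNode(super_id, f"S{si + 1}", f"superregion {si + 1}", parent_id=1, level=2)
        )
        for ci in range(n_children_per):
            leaf_id = next_id
            next_id += 1
            acro = f"S{si + 1}.{ci + 1}"
            nodes.append(OntologyNode(leaf_id, acro, f"area {acro}", parent_id=super_id, level=3))
            zsl = slice(z_edges[si], z_edges[si + 1])
            ysl = slice(y_edges[ci], y_edges[ci + 1])
            if with_layers:
                for li in range(n_layers):
                    layer_id = next_id
                    next_id += 1
                    nodes.append(
                        OntologyNode(
                            layer_id, f"{acro}.L{li + 1}", f"area {acro} layer {li + 1}",
                            parent_id=leaf_id, level=4, layer=f"L{li + 1}",
                        )
                    )
                    annotation[zsl, ysl, x_edges[li]:x_edges[li + 1]] = layer_id
            else:
                annotation[zsl, ysl, 1:shape[2] - 1] = leaf_id

    return AtlasBundle(
        annotation=annotation,
        ontology=Ontology(nodes),
        voxel_size=voxel_size,
        midline_axis=2,
        midline_index=shape[2] // 2,
    )


def generate_training_benchmark(
    n_patches: int = 200,
    patch_shape: tuple[int, int, int] = (32, 32, 32),
    seed: int = 0,
):
    """Standard segmentation benchmark: spot-mask training pairs from phantoms.

    Phantoms are generated, thresholded and rendered into spot masks by the
    training-mask pipeline, then tiled into ``patch_shape`` pairs; the first
    ``n_patches`` are returned.  Used for the scaled-down training benchmark
    and the hybrid-vs-ablated comparison.

    Benchmark phantoms contain cells only: vessels carry no spot-mask ground
    truth (they are handled by the dual-channel filter chain after
    inference), so including them would make the voxel-wise training target
    ill-defined.
    """
    from .config import PipelineConfig
    from .trainmask import build_training_set

    cfg = PipelineConfig(core_shape=patch_shape, seed=seed)
    pairs = []
    phantom_seed = seed
    while len(pairs) < n_patches:
        spec = PhantomSpec(shape=(64, 160, 160), n_cells=150, n_vessels=0, seed=phantom_seed)
        sample = generate_phantom(spec)
        new_pairs, _ = build_training_set([sample], cfg, patch_shape=patch_shape)
        pairs.extend(new_pairs)
        phantom_seed += 1
    return pairs[:n_patches]


@dataclass
class GroupDesign:
    """A planted-effect cohort design over a fixed region list."""

    groups: tuple[str, ...] = ("ctrl", "stress")
    n_per_group: int = 6
    regions: tuple[str, ...] = ()
    baseline_mean: dict[str, float] = field(default_factory=dict)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)  # region -> group -> factor
    sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 animals per group")
        if any(m <= 0 for m in self.baseline_mean.values()):
            raise ValueError("baseline means must be > 0")
        for per_group in self.effects.values():
            if any(f <= 0 for f in per_group.values()):
                raise ValueError("effect factors must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @classmethod
    def planted(
        cls,
        n_regions: int = 100,
        n_effect: int = 20,
        factor: float | tuple[float, float] = (2.0, 3.0),
        n_per_group: int = 6,
        sigma: float = 0.25,
        seed: int = 0,
        baseline_range: tuple[float, float] = (100.0, 2000.0),
    ) -> "GroupDesign":
        """The standard recovery benchmark: ``n_effect`` up-regulated regions.

        ``factor`` is either a single multiplicative effect or an inclusive
        range from which per-region effects are drawn uniformly (default
        2-3x, a mix of effect strengths all at least twofold).
        """
        rng = np.random.default_rng(seed)
        regions = tuple(f"R{i + 1:03d}" for i in range(n_regions))
        baseline = {r: float(np.exp(rng.uniform(*np.log(baseline_range)))) for r in regions}
        effect_regions = rng.choice(n_regions, size=n_effect, replace=False)
        if isinstance(factor, (tuple, list)):
            factors = rng.uniform(factor[0], factor[1], size=n_effect)
        else:
            factors = np.full(n_effect, float(factor))
        effects = {
            regions[i]: {"stress": float(f)}
            for i, f in zip(sorted(effect_regions), factors)
        }
        return cls(
            groups=("ctrl", "stress"),
            n_per_group=n_per_group,
            regions=regions,
            baseline_mean=baseline,
            effects=effects,
            sigma=sigma,
            seed=seed,
        )


def generate_group_counts(design: GroupDesign) -> pd.DataFrame:
    """Draw a tidy (animal, group, region, count) table from a planted design.

    ``count ~ round(lognormal(log(mu_r * f_gr), sigma))`` where ``f_gr`` is the
    planted multiplicative factor (1 outside the effect map).  The planted
    effect regions are recorded in ``df.attrs["effect_regions"]``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in design.groups:
        for a in range(design.n_per_group):
            animal = f"{group}_{a + 1}"
            for region in design.regions:
                mu = design.baseline_mean[region]
                f = design.effects.get(region, {}).get(group, 1.0)
                count = float(np.round(rng.lognormal(np.log(mu * f), design.sigma)))
                rows.append({"animal": animal, "group": group, "region": region, "count": count})
    df = pd.DataFrame(rows)
    df.attrs["effect_regions"] = sorted(design.effects)
    return df
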