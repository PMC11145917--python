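"""Pipeline configuration: typed defaults, validation, YAML/JSON round trip.

Every stage of the pipeline reads its parameters from one
:class:`PipelineConfig`.  Defaults encode the package's documented choices
(e.g. threshold ``mean + 3*SD`` for training-mask generation, soma volume
bounds 50-5000 um^3, volcano cuts ``|fc| > 1.4`` and ``q < 0.05``); unknown
keys and out-of-range values are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["HybridSwinConfig", "PipelineConfig", "load_config", "save_config"]


def _triple(x, name: str) -> tuple[int, int, int]:
    if isinstance(x, int):
        return (x, x, x)
    t = tuple(int(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"{name} must be an int or 3 ints, got {x!r}")
    return t


@dataclass
class HybridSwinConfig:
    """Hyperparameters of the hybrid shifted-window transformer segmenter.

    ``depths`` gives the number of transformer blocks in each of the four
    encoder stages; channel width doubles at each patch merging, so stage
    widths are ``C, 2C, 4C, 8C`` for ``embed_dim = C``.
    """

    in_channels: int = 1
    num_classes: int = 2
    embed_dim: int = 32
    token_patch: tuple[int, int, int] = (2, 2, 2)
    window: tuple[int, int, int] = (4, 4, 4)
    depths: tuple[int, int, int, int] = (2, 2, 6, 2)
    heads: tuple[int, int, int, int] = (2, 4, 8, 16)
    dilation_rates: tuple[int, ...] = (1, 2, 3)
    dilated_block: bool = True  # False = ablated variant (no conv front-end)
    conv_channels: int = 4      # channels per dilated branch
    mlp_ratio: float = 2.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.token_patch = _triple(self.token_patch, "token_patch")
        self.window = _triple(self.window, "window")
        self.depths = tuple(int(d) for d in self.depths)
        self.heads = tuple(int(h) for h in self.heads)
        self.dilation_rates = tuple(int(r) for r in self.dilation_rates)
        if len(self.depths) != 4:
            raise ValueError(f"depths must have 4 stages, got {self.depths}")
        if len(self.heads) != 4:
            raise ValueError(f"heads must have 4 stages, got {self.heads}")
        if self.embed_dim < 1 or self.embed_dim % max(self.heads) != 0:
            # widths double per stage, so divisibility by stage-1 heads suffices;
            # requiring divisibility by the largest head count keeps every stage valid
            raise ValueError(
                f"embed_dim {self.embed_dim} must be a positive multiple of max heads {max(self.heads)}"
            )
        if any(d < 1 for d in self.depths) or any(h < 1 for h in self.heads):
            raise ValueError("depths and heads must all be >= 1")
        if any(p < 1 for p in self.token_patch) or any(w < 1 for w in self.window):
            raise ValueError("token_patch and window components must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.in_channels != 1:
            raise ValueError("only single-channel input is supported")
        if self.num_classes != 2:
            raise ValueError("only two-class (foreground/background) output is supported")

    def validate_input_shape(self, shape: tuple[int, int, int]) -> None:
        """Input patch spatial dims must survive token embedding + 3 mergings."""
        for ax, (s, p) in enumerate(zip(shape, self.token_patch)):
            if s % (p * 8) != 0:
                raise ValueError(
                    f"axis {ax}: input extent {s} not divisible by token_patch*8 = {p * 8}"
                )


@dataclass
class PipelineConfig:
    """All tunable parameters of the segmentation/quantification pipeline."""

    # tiling
    core_shape: tuple[int, int, int] = (64, 64, 64)
    halo: int = 8
    voxel_size: tuple[float, float, float] = (3.5, 1.0, 1.0)  # (dz, dy, dx) um
    # training-mask generation
    k_thresh: float = 3.0
    spot_radius_um: float = 4.0
    min_separation_um: float = 5.0
    # model
    model: HybridSwinConfig = field(default_factory=HybridSwinConfig)
    # post-processing filters
    af_overlap_frac: float = 0.5
    soma_volume_um3_min: float = 50.0
    soma_volume_um3_max: float = 5000.0
    intensity_k: float = 3.0
    # statistics
    fc_cut: float = 1.4
    q_cut: float = 0.05
    cv_ddof: int = 1
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.core_shape = _triple(self.core_shape, "core_shape")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if isinstance(self.model, dict):
            self.model = _from_mapping(HybridSwinConfig, self.model)
        checks = [
            (all(c >= 1 for c in self.core_shape), "core_shape components must be >= 1"),
            (self.halo >= 0, f"halo must be >= 0, got {self.halo}"),
            (all(v > 0 for v in self.voxel_size), "voxel_size components must be > 0"),
            (self.k_thresh >= 0, f"k_thresh must be >= 0, got {self.k_thresh}"),
            (self.spot_radius_um > 0, f"spot_radius_um must be > 0, got {self.spot_radius_um}"),
            (self.min_separation_um > 0, f"min_separation_um must be > 0, got {self.min_separation_um}"),
            (0 < self.af_overlap_frac <= 1, f"af_overlap_frac must be in (0, 1], got {self.af_overlap_frac}"),
            (0 < self.soma_volume_um3_min < self.soma_volume_um3_max,
             "soma volume bounds must satisfy 0 < min < max"),
            (self.intensity_k >= 0, f"intensity_k must be >= 0, got {self.intensity_k}"),
            (self.fc_cut >= 1, f"fc_cut must be >= 1, got {self.fc_cut}"),
            (0 < self.q_cut <= 1, f"q_cut must be in (0, 1], got {self.q_cut}"),
            (self.cv_ddof in (0, 1), f"cv_ddof must be 0 or 1, got {self.cv_ddof}"),
            (self.seed >= 0, f"seed must be >= 0, got {self.seed}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, tuple):
                return [plain(v) for v in x]
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            return x

        return plain(dataclasses.asdict(self))


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | os.PathLike | None = None, mapping: dict | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON document.

    Absent keys take documented defaults; unknown keys or out-of-range values
    raise ``ValueError``.  An empty document yields the all-defaults config.
    """
    if mapping is None:
        with open(os.fspath(path)) as fh:
            text = fh.read()
        mapping = yaml.safe_load(text) or {}  # YAML is a superset of JSON
    if not isinstance(mapping, dict):
        raise ValueError("config document must be a mapping")
    return _from_mapping(PipelineConfig, mapping)


def save_config(cfg: PipelineConfig, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    doc = cfg.to_dict()
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh)
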