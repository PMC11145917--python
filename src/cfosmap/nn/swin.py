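"""Hybrid 3D shifted-window transformer for voxel-wise two-class segmentation.

The network is U-shaped.  A dilated convolution front-end (three parallel
3x3x3 convolutions at dilation rates 1/2/3, concatenated and fused by a 1^3
convolution) injects multi-scale local context before tokenisation; patch
partition plus a linear embedding turns the volume into a token grid.  The
encoder has four stages of shifted-window transformer blocks with block
counts ``depths`` (default ``(2, 2, 6, 2)``); patch merging between stages
halves each spatial axis and doubles the channel width, giving stage widths
``C, 2C, 4C, 8C``.  The deepest stage doubles as the bottleneck.  The decoder
mirrors the encoder with three patch-expanding steps, each fused with the
matching encoder stage through a skip connection (channel concatenation +
linear reduction); a final expansion restores the input resolution and a
linear projection plus softmax yields per-voxel class probabilities.

Attention is multi-head self-attention inside non-overlapping 3D windows;
alternate blocks shift the window grid by half a window (cyclic roll) and
mask attention between voxels that are not spatial neighbours after the
wrap-around, exactly as in the shifted-window scheme.  Window sizes are
clamped to the token grid at deep stages (and the shift disabled there).

Setting ``dilated_block=False`` builds the ablated variant without the
convolution front-end (tokens are embedded straight from the input volume),
used for the hybrid-vs-plain comparison.
"""

from __future__ import annotations

import numpy as np

from ..config import HybridSwinConfig
from .autodiff import Tensor, concat, conv3d_same

__all__ = ["HybridSwinUNet3D", "build_model", "forward"]


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Linear:
    def __init__(self, rng, d_in: int, d_out: int, name: str):
        # fan-in-scaled truncated normal: keeps activation scale near unity
        # at the small widths this CPU-scale model uses
        std = min(0.05, d_in**-0.5)
        self.w = Tensor(_trunc_normal(rng, (d_in, d_out), std=std), requires_grad=True, name=f"{name}.w")
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True, name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        # flatten to one 2D GEMM: much faster than a batched matmul loop
        lead = x.shape[:-1]
        out = x.reshape(-1, x.shape[-1]) @ self.w + self.b
        return out.reshape(*lead, self.w.shape[-1])

    def params(self):
        return [self.w, self.b]


class LayerNorm:
    def __init__(self, dim: int, name: str):
        self.g = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True, name=f"{name}.g")
        self.b = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True, name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.g, self.b)

    def params(self):
        return [self.g, self.b]


class Mlp:
    def __init__(self, rng, dim: int, ratio: float, name: str):
        hidden = int(dim * ratio)
        self.fc1 = Linear(rng, dim, hidden, f"{name}.fc1")
        self.fc2 = Linear(rng, hidden, dim, f"{name}.fc2")

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())

    def params(self):
        return self.fc1.params() + self.fc2.params()


def _window_partition(x: Tensor, grid, window) -> Tensor:
    """(B, D, H, W, C) -> (B * n_windows, prod(window), C)."""
    B = x.shape[0]
    C = x.shape[-1]
    nd, nh, nw = (grid[a] // window[a] for a in range(3))
    x = x.reshape(B, nd, window[0], nh, window[1], nw, window[2], C)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return x.reshape(B * nd * nh * nw, window[0] * window[1] * window[2], C)


def _window_reverse(x: Tensor, B: int, grid, window, C: int) -> Tensor:
    nd, nh, nw = (grid[a] // window[a] for a in range(3))
    x = x.reshape(B, nd, nh, nw, window[0], window[1], window[2], C)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return x.reshape(B, grid[0], grid[1], grid[2], C)


def _attention_mask(grid, window, shift) -> np.ndarray | None:
    """Additive mask (n_windows, T, T) blocking attention across wrapped regions."""
    if all(s == 0 for s in shift):
        return None
    ids = np.zeros(grid, dtype=np.int64)
    cnt = 0
    ranges = []
    for a in range(3):
        w, s = window[a], shift[a]
        if s == 0:
            ranges.append([slice(0, grid[a])])
        else:
            ranges.append([slice(0, grid[a] - w), slice(grid[a] - w, grid[a] - s), slice(grid[a] - s, grid[a])])
    for rz in ranges[0]:
        for ry in ranges[1]:
            for rx in ranges[2]:
                ids[rz, ry, rx] = cnt
                cnt += 1
    ids = np.roll(ids, tuple(-s for s in shift), axis=(0, 1, 2))
    nd, nh, nw = (grid[a] // window[a] for a in range(3))
    ids = ids.reshape(nd, window[0], nh, window[1], nw, window[2])
    ids = ids.transpose(0, 2, 4, 1, 3, 5).reshape(nd * nh * nw, -1)
    mask = np.where(ids[:, :, None] == ids[:, None, :], 0.0, -1e4).astype(np.float32)
    return mask


class WindowAttention:
    def __init__(self, rng, dim: int, heads: int, name: str):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.scale = self.head_dim**-0.5
        self.q = Linear(rng, dim, dim, f"{name}.q")
        self.k = Linear(rng, dim, dim, f"{name}.k")
        self.v = Linear(rng, dim, dim, f"{name}.v")
        self.proj = Linear(rng, dim, dim, f"{name}.proj")

    def _heads(self, t: Tensor, nW: int, T: int) -> Tensor:
        return t.reshape(nW, T, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, mask: np.ndarray | None, batch: int) -> Tensor:
        nW, T, C = x.shape
        q = self._heads(self.q(x), nW, T)
        k = self._heads(self.k(x), nW, T)
        v = self._heads(self.v(x), nW, T)
        attn = (q * self.scale) @ k.transpose(0, 1, 3, 2)
        if mask is not None:
            nwin = mask.shape[0]
            attn = attn.reshape(batch, nwin, self.heads, T, T) + Tensor(mask[None, :, None])
            attn = attn.reshape(nW, self.heads, T, T)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nW, T, C)
        return self.proj(out)

    def params(self):
        return self.q.params() + self.k.params() + self.v.params() + self.proj.params()


class SwinBlock:
    """Pre-norm transformer block with (optionally shifted) window attention."""

    def __init__(self, rng, dim: int, heads: int, window, shifted: bool, mlp_ratio: float, name: str):
        self.window = tuple(window)
        self.shifted = shifted
        self.norm1 = LayerNorm(dim, f"{name}.norm1")
        self.attn = WindowAttention(rng, dim, heads, f"{name}.attn")
        self.norm2 = LayerNorm(dim, f"{name}.norm2")
        self.mlp = Mlp(rng, dim, mlp_ratio, f"{name}.mlp")
        self._mask_cache: dict = {}

    def _geometry(self, grid):
        window = tuple(min(w, g) for w, g in zip(self.window, grid))
        for ax in range(3):
            if grid[ax] % window[ax]:
                raise ValueError(
                    f"axis {ax}: window {window[ax]} does not divide token grid {grid[ax]}"
                )
        shift = tuple(
            (w // 2 if (self.shifted and w < g and w > 1) else 0)
            for w, g in zip(window, grid)
        )
        return window, shift

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        grid = x.shape[1:4]
        C = x.shape[-1]
        window, shift = self._geometry(grid)
        key = (grid, window, shift)
        if key not in self._mask_cache:
            self._mask_cache[key] = _attention_mask(grid, window, shift)
        mask = self._mask_cache[key]

        y = self.norm1(x)
        if any(shift):
            y = y.roll(tuple(-s for s in shift), axes=(1, 2, 3))
        y = _window_partition(y, grid, window)
        y = self.attn(y, mask, B)
        y = _window_reverse(y, B, grid, window, C)
        if any(shift):
            y = y.roll(shift, axes=(1, 2, 3))
        x = x + y
        return x + self.mlp(self.norm2(x))

    def params(self):
        return self.norm1.params() + self.attn.params() + self.norm2.params() + self.mlp.params()


class PatchMerging:
    """2x downsampling of the token grid; channel width doubles."""

    def __init__(self, rng, dim: int, name: str):
        self.dim = dim
        self.norm = LayerNorm(8 * dim, f"{name}.norm")
        self.reduce = Linear(rng, 8 * dim, 2 * dim, f"{name}.reduce")

    def __call__(self, x: Tensor) -> Tensor:
        B, D, H, W, C = x.shape
        x = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(B, D // 2, H // 2, W // 2, 8 * C)
        return self.reduce(self.norm(x))

    def params(self):
        return self.norm.params() + self.reduce.params()


class PatchExpanding:
    """2x upsampling of the token grid with a target channel width."""

    def __init__(self, rng, dim_in: int, dim_out: int, name: str):
        self.dim_out = dim_out
        self.expand = Linear(rng, dim_in, 8 * dim_out, f"{name}.expand")

    def __call__(self, x: Tensor) -> Tensor:
        B, D, H, W, _ = x.shape
        x = self.expand(x).reshape(B, D, H, W, 2, 2, 2, self.dim_out)
        x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return x.reshape(B, 2 * D, 2 * H, 2 * W, self.dim_out)

    def params(self):
        return self.expand.params()


class DilatedConvBlock:
    """Parallel dilated 3D convolutions fused by a pointwise convolution."""

    def __init__(self, rng, in_ch: int, branch_ch: int, rates, name: str):
        self.rates = tuple(rates)
        self.branches = [
            (
                Tensor(_trunc_normal(rng, (branch_ch, in_ch, 3, 3, 3), std=0.1),
                       requires_grad=True, name=f"{name}.w{r}"),
                Tensor(np.zeros(branch_ch, dtype=np.float32), requires_grad=True, name=f"{name}.b{r}"),
                r,
            )
            for r in self.rates
        ]
        fused_in = branch_ch * len(self.rates)
        self.fuse_w = Tensor(
            _trunc_normal(rng, (in_ch + branch_ch, fused_in, 1, 1, 1), std=0.1),
            requires_grad=True, name=f"{name}.fuse_w",
        )
        self.fuse_b = Tensor(
            np.zeros(in_ch + branch_ch, dtype=np.float32), requires_grad=True, name=f"{name}.fuse_b"
        )
        self.out_channels = in_ch + branch_ch

    def __call__(self, x: Tensor) -> Tensor:
        feats = [conv3d_same(x, w, b, dilation=r).gelu() for w, b, r in self.branches]
        fused = conv3d_same(concat(feats, axis=1), self.fuse_w, self.fuse_b, dilation=1)
        return fused

    def params(self):
        out = []
        for w, b, _ in self.branches:
            out += [w, b]
        return out + [self.fuse_w, self.fuse_b]


class PatchEmbed:
    """Non-overlapping patch partition + linear embedding of each patch."""

    def __init__(self, rng, in_ch: int, patch, dim: int, name: str):
        self.patch = tuple(patch)
        self.in_ch = in_ch
        p = int(np.prod(self.patch))
        self.proj = Linear(rng, p * in_ch, dim, f"{name}.proj")
        self.norm = LayerNorm(dim, f"{name}.norm")

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C, D, H, W) -> token grid (B, D/p, H/p, W/p, dim)
        B, C, D, H, W = x.shape
        pz, py, px = self.patch
        x = x.transpose(0, 2, 3, 4, 1)
        x = x.reshape(B, D // pz, pz, H // py, py, W // px, px, C)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        x = x.reshape(B, D // pz, H // py, W // px, pz * py * px * C)
        return self.norm(self.proj(x))

    def params(self):
        return self.proj.params() + self.norm.params()


class HybridSwinUNet3D:
    """The full U-shaped hybrid shifted-window transformer."""

    def __init__(self, cfg: HybridSwinConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C = cfg.embed_dim

        if cfg.dilated_block:
            self.conv_block = DilatedConvBlock(
                rng, cfg.in_channels, cfg.conv_channels, cfg.dilation_rates, "conv"
            )
            embed_in = self.conv_block.out_channels
        else:
            self.conv_block = None
            embed_in = cfg.in_channels
        self.embed = PatchEmbed(rng, embed_in, cfg.token_patch, C, "embed")

        self.stage_widths = tuple(C * 2**i for i in range(4))
        self.encoder_stages: list[list[SwinBlock]] = []
        self.mergings: list[PatchMerging] = []
        for s in range(4):
            dim = self.stage_widths[s]
            blocks = [
                SwinBlock(
                    rng, dim, cfg.heads[s], cfg.window, shifted=(b % 2 == 1),
                    mlp_ratio=cfg.mlp_ratio, name=f"enc{s}.blk{b}",
                )
                for b in range(cfg.depths[s])
            ]
            self.encoder_stages.append(blocks)
            if s < 3:
                self.mergings.append(PatchMerging(rng, dim, f"merge{s}"))

        # decoder: three expand+fuse steps back up to stage-1 resolution
        self.expandings: list[PatchExpanding] = []
        self.skip_fusions: list[Linear] = []
        self.decoder_stages: list[list[SwinBlock]] = []
        for s in (2, 1, 0):
            dim = self.stage_widths[s]
            self.expandings.append(PatchExpanding(rng, 2 * dim, dim, f"expand{s}"))
            self.skip_fusions.append(Linear(rng, 2 * dim, dim, f"fuse{s}"))
            self.decoder_stages.append(
                [
                    SwinBlock(
                        rng, dim, cfg.heads[s], cfg.window, shifted=(b % 2 == 1),
                        mlp_ratio=cfg.mlp_ratio, name=f"dec{s}.blk{b}",
                    )
                    for b in range(cfg.depths[s])
                ]
            )
        self.final_expand = PatchExpanding(rng, C, C, "final_expand")  # token -> voxel grid
        # voxel-resolution skip into the head: token features alone are
        # constant over each token block, so per-voxel boundaries need the
        # full-resolution front-end features (raw voxel for the ablated variant)
        self._front_channels = embed_in
        self.head = Linear(rng, C + embed_in, cfg.num_classes, "head")

        self._params = self._collect_params()

    # -- contract introspection -------------------------------------------
    @property
    def num_stages(self) -> int:
        return len(self.encoder_stages)

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.encoder_stages)

    @property
    def num_skips(self) -> int:
        return len(self.skip_fusions)

    def _collect_params(self):
        layers = []
        if self.conv_block is not None:
            layers.append(self.conv_block)
        layers.append(self.embed)
        for blocks in self.encoder_stages:
            layers += blocks
        layers += self.mergings
        layers += self.expandings
        layers += self.skip_fusions
        for blocks in self.decoder_stages:
            layers += blocks
        layers += [self.final_expand, self.head]
        params = []
        for layer in layers:
            if isinstance(layer, Linear):
                params += layer.params()
            else:
                params += layer.params()
        return params

    def parameters(self) -> list[Tensor]:
        return self._params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params))

    def token_grids(self, input_shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        """Token-grid extent at each encoder stage for a given input patch shape."""
        self.cfg.validate_input_shape(input_shape)
        grid = tuple(s // p for s, p in zip(input_shape, self.cfg.token_patch))
        grids = [grid]
        for _ in range(3):
            grid = tuple(g // 2 for g in grid)
            grids.append(grid)
        return grids

    # -- forward -----------------------------------------------------------
    def forward_batch(self, batch: np.ndarray) -> Tensor:
        """(B, D, H, W) normalised intensities -> (B, D, H, W, n_classes) probabilities."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 4:
            raise ValueError(f"expected (B, D, H, W) input, got shape {batch.shape}")
        self.cfg.validate_input_shape(batch.shape[1:])
        x = Tensor(batch[:, None])  # (B, 1, D, H, W)
        if self.conv_block is not None:
            x = self.conv_block(x)
        front = x.transpose(0, 2, 3, 4, 1)  # voxel-resolution features for the head skip
        x = self.embed(x)

        skips = []
        for s in range(4):
            for blk in self.encoder_stages[s]:
                x = blk(x)
            if s < 3:
                skips.append(x)
                x = self.mergings[s](x)
        # deepest stage (bottleneck) output is in x; decode with 3 skips
        for expand, fuse, blocks, skip in zip(
            self.expandings, self.skip_fusions, self.decoder_stages, skips[::-1]
        ):
            x = expand(x)
            x = fuse(concat([x, skip], axis=-1))
            for blk in blocks:
                x = blk(x)
        x = self.final_expand(x)
        logits = self.head(concat([x, front], axis=-1))
        return logits.softmax(axis=-1)

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Normalised forward + argmax -> binary mask for one (D, H, W) patch."""
        probs = forward(self, patch)
        return (probs[..., 1] > probs[..., 0]).astype(np.uint8)

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self._params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self._params:
            if p.name not in state:
                raise ValueError(f"missing parameter {p.name} in checkpoint")
            if state[p.name].shape != p.data.shape:
                raise ValueError(
                    f"parameter {p.name}: checkpoint shape {state[p.name].shape} "
                    f"!= model shape {p.data.shape}"
                )
            p.data = state[p.name].astype(np.float32).copy()


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Per-patch min-max normalisation to [0, 1] (constant patches map to 0)."""
    patch = np.asarray(patch, dtype=np.float32)
    lo, hi = float(patch.min()), float(patch.max())
    if hi == lo:
        return np.zeros_like(patch)
    return (patch - lo) / (hi - lo)


def build_model(cfg: HybridSwinConfig | None = None) -> HybridSwinUNet3D:
    """Construct the segmentation network from a hyperparameter config."""
    return HybridSwinUNet3D(cfg or HybridSwinConfig())


def forward(model: HybridSwinUNet3D, patch: np.ndarray, second_patch: np.ndarray | None = None):
    """Run inference on one patch (optionally batched with a second).

    Patches are min-max normalised per patch; the returned array(s) have the
    input spatial shape plus a trailing class axis with probabilities
    summing to one per voxel.
    """
    patches = [normalize_patch(patch)]
    if second_patch is not None:
        patches.append(normalize_patch(second_patch))
    probs = model.forward_batch(np.stack(patches)).data
    if second_patch is None:
        return probs[0]
    return probs[0], probs[1]
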