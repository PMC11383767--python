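"""Hierarchical shifted-window transformer backbone.

The base classifier follows the standard tiny configuration: 4x4 patch
embedding to 96 channels, four stages of depths (2, 2, 6, 2) with
(3, 6, 12, 24) attention heads, 7x7 attention windows alternating between
window attention (W-MSA) and shifted-window attention (SW-MSA, cyclic shift
of floor(M/2) with the 9-region additive mask), patch merging between
stages, and a layer-norm / global-average-pool / linear classification head.

Token grids are carried as (batch, grid_h, grid_w, channels) tensors so the
spatial shape stays explicit throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import LayerNorm, Linear, Module, Parameter, trunc_normal

__all__ = [
    "SwinConfig",
    "SwinClassifier",
    "window_partition",
    "window_reverse",
    "shifted_window_mask",
    "attention_flops",
    "normalize_image",
    "WindowAttention",
    "PatchEmbed",
    "PatchMerging",
    "SwinBlock",
]

MASK_FILL = -1e9  # additive logit for forbidden cross-region pairs


@dataclass(frozen=True)
class SwinConfig:
    """Backbone hyperparameters (defaults: the 3-class tiny configuration)."""

    img_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: float = 4.0
    num_classes: int = 3
    qkv_bias: bool = True
    norm_mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    norm_std: tuple[float, float, float] = (0.229, 0.224, 0.225)

    @property
    def shift_size(self) -> int:
        return self.window_size // 2

    @property
    def num_stages(self) -> int:
        return len(self.depths)

    def stage_dims(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * 2 ** i for i in range(self.num_stages))

    def stage_grids(self) -> tuple[int, ...]:
        g = self.img_size // self.patch_size
        return tuple(g // 2 ** i for i in range(self.num_stages))

    def validate(self) -> None:
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must have equal length")
        if self.img_size % self.patch_size != 0:
            raise ValueError("img_size must be divisible by patch_size")
        for i, g in enumerate(self.stage_grids()):
            if g % self.window_size != 0:
                raise ValueError(
                    f"stage {i + 1} grid {g} not divisible by window {self.window_size}")
        for dim, heads in zip(self.stage_dims(), self.num_heads):
            if dim % heads != 0:
                raise ValueError("channel dim must be divisible by head count")
        if not (0 <= self.shift_size < self.window_size):
            raise ValueError("shift must lie in [0, window)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SwinConfig":
        raw = json.loads(text)
        for key in ("depths", "num_heads", "norm_mean", "norm_std"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def normalize_image(img: np.ndarray, cfg: SwinConfig) -> np.ndarray:
    """uint8 HxWx3 (or NxHxWx3) -> standardized float32, same layout."""
    arr = np.asarray(img, dtype=np.float32) / 255.0
    mean = np.asarray(cfg.norm_mean, dtype=np.float32)
    std = np.asarray(cfg.norm_std, dtype=np.float32)
    return (arr - mean) / std


# ------------------------------------------------------------------ windows

def window_partition(x: Tensor, window: int) -> Tensor:
    """(B, H, W, C) -> (B * nWindows, window*window, C)."""
    B, H, W, C = x.shape
    if H % window or W % window:
        raise ValueError(f"grid {H}x{W} not divisible by window {window}")
    x = x.reshape(B, H // window, window, W // window, window, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(-1, window * window, C)


def window_reverse(windows: Tensor, window: int, H: int, W: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    nW = (H // window) * (W // window)
    B = windows.shape[0] // nW
    x = windows.reshape(B, H // window, W // window, window, window, -1)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, x.shape[-1])


def shifted_window_mask(grid_h: int, grid_w: int, window: int, shift: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Region-id grid and additive attention mask for SW-MSA.

    After the cyclic shift by (-shift, -shift) the grid decomposes into
    3 x 3 = 9 contiguous regions (row bands x column bands); tokens sharing
    a window but originating from different pre-shift regions must not
    attend to each other.  Returns ``(region_ids (H, W) int array,
    mask (nWindows, window**2, window**2) float array of {0, MASK_FILL})``.
    """
    if not (0 <= shift < window):
        raise ValueError("shift must lie in [0, window)")
    region = np.zeros((grid_h, grid_w), dtype=np.int64)
    if shift == 0:
        n_windows = (grid_h // window) * (grid_w // window)
        return region, np.zeros((n_windows, window ** 2, window ** 2), dtype=np.float32)
    bands = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    cnt = 0
    for hs in bands:
        for ws in bands:
            region[hs, ws] = cnt
            cnt += 1
    r = region.reshape(grid_h // window, window, grid_w // window, window)
    r = r.transpose(0, 2, 1, 3).reshape(-1, window * window)
    diff = r[:, :, None] != r[:, None, :]
    mask = np.where(diff, np.float32(MASK_FILL), np.float32(0.0))
    return region, mask


def attention_flops(H: int, W: int, C: int, M: int | None = None,
                    windowed: bool = False) -> int:
    """Multiply-accumulate count of one attention layer.

    Global attention costs ``4 H W C^2 + 2 (H W)^2 C``; window attention
    replaces the quadratic token term with the window area:
    ``4 H W C^2 + 2 M^2 H W C``.
    """
    if windowed:
        if M is None:
            raise ValueError("windowed=True requires the window size M")
        return 4 * H * W * C * C + 2 * M * M * H * W * C
    return 4 * H * W * C * C + 2 * (H * W) ** 2 * C


# ------------------------------------------------------------------ modules

class PatchEmbed(Module):
    """Non-overlapping p x p patches, linear projection, layer norm."""

    def __init__(self, cfg: SwinConfig, rng: np.random.Generator):
        super().__init__()
        p = cfg.patch_size
        self.patch_size = p
        self.proj = Linear(p * p * 3, cfg.embed_dim, rng)
        self.norm = LayerNorm(cfg.embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        p = self.patch_size
        if H % p or W % p:
            raise ValueError(f"input {H}x{W} not divisible by patch size {p}")
        x = x.reshape(B, H // p, p, W // p, p, C)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // p, W // p, p * p * C)
        return self.norm(self.proj(x))


class WindowAttention(Module):
    """Multi-head self-attention inside one window with relative position bias."""

    def __init__(self, dim: int, num_heads: int, window: int,
                 rng: np.random.Generator, qkv_bias: bool = True):
        super().__init__()
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window = window
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng, bias=qkv_bias)
        self.proj = Linear(dim, dim, rng)
        self.relative_bias_table = Parameter(
            trunc_normal(rng, ((2 * window - 1) ** 2, num_heads)))
        self._bias_index = self._relative_index(window)

    @staticmethod
    def _relative_index(window: int) -> np.ndarray:
        coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :]  # (2, N, N)
        rel = rel + (window - 1)
        return rel[0] * (2 * window - 1) + rel[1]  # (N, N) in [0, (2M-1)^2)

    def forward(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        Bw, N, C = xw.shape
        h, d = self.num_heads, self.head_dim
        qkv = self.qkv(xw).reshape(Bw, N, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (Bw, h, N, d)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale  # (Bw, h, N, N)
        bias = self.relative_bias_table[self._bias_index.reshape(-1)]
        bias = bias.reshape(N, N, h).transpose(2, 0, 1)
        attn = attn + bias
        if mask is not None:
            nW = mask.shape[0]
            if mask.shape[1:] != (N, N):
                raise ValueError("attention mask shape mismatch")
            attn = attn.reshape(Bw // nW, nW, h, N, N) + mask[None, :, None]
            attn = attn.reshape(Bw, h, N, N)
        attn = ad.softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(Bw, N, C)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class SwinBlock(Module):
    """Pre-norm transformer block with (shifted-)window attention."""

    def __init__(self, dim: int, num_heads: int, window: int, shift: int,
                 grid: int, mlp_ratio: float, rng: np.random.Generator,
                 qkv_bias: bool = True):
        super().__init__()
        self.window = window
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window, rng, qkv_bias)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        if shift:
            _, self.attn_mask = shifted_window_mask(grid, grid, window, shift)
        else:
            self.attn_mask = None

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        shortcut = x
        x = self.norm1(x)
        if self.shift:
            x = ad.roll(x, (-self.shift, -self.shift), axis=(1, 2))
        windows = window_partition(x, self.window)
        windows = self.attn(windows, self.attn_mask)
        x = window_reverse(windows, self.window, H, W)
        if self.shift:
            x = ad.roll(x, (self.shift, self.shift), axis=(1, 2))
        x = shortcut + x
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    """2x2 token concatenation (4C) -> layer norm -> linear 4C -> 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError("patch merging requires even grid dimensions")
        x = ad.concatenate(
            [x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :],
             x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :]], axis=-1)
        return self.reduction(self.norm(x))


class SwinClassifier(Module):
    """The base hierarchical windowed-attention classifier."""

    def __init__(self, cfg: SwinConfig, rng: np.random.Generator | int | None = None):
        super().__init__()
        cfg.validate()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.patch_embed = PatchEmbed(cfg, rng)
        dims = cfg.stage_dims()
        grids = cfg.stage_grids()
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerging] = []
        for s in range(cfg.num_stages):
            blocks = []
            for b in range(cfg.depths[s]):
                shift = 0 if b % 2 == 0 else cfg.shift_size
                blocks.append(SwinBlock(dims[s], cfg.num_heads[s], cfg.window_size,
                                        shift, grids[s], cfg.mlp_ratio, rng,
                                        cfg.qkv_bias))
            self.stages.append(blocks)
            if s < cfg.num_stages - 1:
                self.merges.append(PatchMerging(dims[s], rng))
        self.norm = LayerNorm(dims[-1])
        self.head = Linear(dims[-1], cfg.num_classes, rng)
        self.cache: dict[str, Tensor] = {}

    def forward_features(self, x: Tensor) -> Tensor:
        """Normalized image batch (B, H, W, 3) -> final token grid."""
        self.cache = {}
        x = self.patch_embed(x)
        for s, blocks in enumerate(self.stages):
            self.cache[f"stage{s + 1}_input"] = x
            for block in blocks:
                x = block(x)
            self.cache[f"stage{s + 1}_output"] = x
            if s < len(self.merges):
                x = self.merges[s](x)
        return x

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = ad.astensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        grid = self.forward_features(x)
        grid = self.norm(grid)
        self.cache["final_tokens"] = grid
        pooled = grid.reshape(grid.shape[0], -1, grid.shape[-1]).mean(axis=1)
        return self.head(pooled)
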