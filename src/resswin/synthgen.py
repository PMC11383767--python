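"""Procedural generator of labelled synthetic cotton-leaf pest images.

The real field dataset behind this work is not publicly deposited, so this
module renders a stand-in: a green leaf blade with veins over soil-and-weed
clutter, plus one of three class-specific damage motifs.

* ``aphid`` — curl-like shading ridges along the leaf rim and clustered
  white/black dots (aphid colonies);
* ``mite`` — scattered yellow-white stipples and a reddening patch whose
  area grows with motif intensity;
* ``mirid`` — sparse black feeding spots and ragged holes punched through
  the blade ("broken leaf"), with necrotic rims.

Everything is drawn from a seeded generator: the same (seed, class, index)
always yields byte-identical pixels.  At ``motif_intensity=0`` the motif
layer is skipped entirely, so the three classes are indistinguishable in
expectation and any classifier should sit at chance — the generator carries
class signal only through the motifs, never through the background.

These images emulate the *structure* of field data (class-conditional local
lesions on a textured, cluttered scene), not its photographic statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dataset import CLASS_LABELS, new_manifest, save_manifest
from .imaging import write_image

__all__ = ["SynthConfig", "generate_leaf_image", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    per_class_counts: tuple[int, int, int] = (1112, 703, 890)
    image_size: int = 448
    seed: int = 0
    clutter_level: float = 0.7
    motif_intensity: float = 1.0

    def __post_init__(self):
        if any(c < 0 for c in self.per_class_counts):
            raise ValueError("per-class counts must be nonnegative")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if not (0.0 <= self.clutter_level <= 1.0):
            raise ValueError("clutter_level must lie in [0, 1]")
        if not (0.0 <= self.motif_intensity <= 1.0):
            raise ValueError("motif_intensity must lie in [0, 1]")


# ------------------------------------------------------------------ helpers

def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Low-pass filtered white noise rescaled to [0, 1]."""
    field = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo + 1e-12)


def _coords(size: int) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(size, dtype=np.float64),
                       np.arange(size, dtype=np.float64), indexing="ij")


def _blob_mask(rng: np.random.Generator, size: int, cy: float, cx: float,
               radius: float, wobble: float = 0.25, n_harm: int = 5) -> np.ndarray:
    """Irregular star-convex blob: r(theta) = radius * (1 + wobble * harmonics)."""
    yy, xx = _coords(size)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r_theta = np.ones_like(theta)
    for h in range(1, n_harm + 1):
        amp = wobble * rng.uniform(0.2, 1.0) / h
        phase = rng.uniform(0, 2 * np.pi)
        r_theta += amp * np.cos(h * theta + phase)
    return np.hypot(dy, dx) < radius * r_theta


def _paint_disk(img: np.ndarray, cy: int, cx: int, radius: int,
                color: np.ndarray) -> None:
    """Paint a small filled disk in place (clipped at borders)."""
    size = img.shape[0]
    lo_y, hi_y = max(0, cy - radius), min(size, cy + radius + 1)
    lo_x, hi_x = max(0, cx - radius), min(size, cx + radius + 1)
    if lo_y >= hi_y or lo_x >= hi_x:
        return
    yy, xx = np.meshgrid(np.arange(lo_y, hi_y), np.arange(lo_x, hi_x), indexing="ij")
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    img[lo_y:hi_y, lo_x:hi_x][disk] = color


# ----------------------------------------------------------------- renderer

def _render_background(rng: np.random.Generator, size: int,
                       clutter: float) -> np.ndarray:
    soil = np.empty((size, size, 3), dtype=np.float64)
    tex = _smooth_noise(rng, size, sigma=size / 16)
    grain = _smooth_noise(rng, size, sigma=1.0)
    base = np.array([128.0, 96.0, 66.0]) + rng.uniform(-12, 12, size=3)
    for c in range(3):
        soil[..., c] = base[c] * (0.7 + 0.5 * tex) + 22.0 * clutter * (grain - 0.5)
    # distractor weed/leaf fragments around the edges of the frame
    n_frag = rng.integers(0, max(1, int(round(6 * clutter)) + 1))
    for _ in range(n_frag):
        edge_bias = rng.uniform(0.0, 0.25)
        side = rng.integers(4)
        pos = rng.uniform(0.1, 0.9) * size
        off = edge_bias * size
        cy, cx = [(off, pos), (size - off, pos), (pos, off), (pos, size - off)][side]
        frag = _blob_mask(rng, size, cy, cx, rng.uniform(0.05, 0.12) * size,
                          wobble=0.4)
        green = np.array([55.0, 105.0, 50.0]) + rng.uniform(-18, 18, size=3)
        soil[frag] = 0.3 * soil[frag] + 0.7 * green
    return soil


def _leaf_geometry(rng: np.random.Generator, size: int
                   ) -> tuple[np.ndarray, np.ndarray, tuple[float, float], float]:
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    radius = rng.uniform(0.30, 0.38) * size
    mask = _blob_mask(rng, size, cy, cx, radius, wobble=0.18, n_harm=4)
    yy, xx = _coords(size)
    dist_edge = ndimage.distance_transform_edt(mask)
    return mask, dist_edge, (cy, cx), radius


def _paint_leaf(rng: np.random.Generator, img: np.ndarray, mask: np.ndarray,
                dist_edge: np.ndarray, centre: tuple[float, float]) -> None:
    size = img.shape[0]
    base = np.array([52.0, 116.0, 48.0]) + rng.uniform(-10, 10, size=3)
    shade = _smooth_noise(rng, size, sigma=size / 10)
    for c in range(3):
        layer = base[c] * (0.8 + 0.4 * shade)
        img[..., c][mask] = layer[mask]
    # veins: a main midrib and lateral branches, drawn as thin dark paths
    cy, cx = centre
    angle = rng.uniform(0, np.pi)
    vein_color = base * 0.72
    n_pts = 4 * size
    t = np.linspace(-0.45 * size, 0.45 * size, n_pts)
    main_y = np.clip(np.rint(cy + t * np.sin(angle)), 0, size - 1).astype(int)
    main_x = np.clip(np.rint(cx + t * np.cos(angle)), 0, size - 1).astype(int)
    sel = mask[main_y, main_x]
    img[main_y[sel], main_x[sel]] = vein_color
    for k in range(6):
        frac = (k + 1) / 7.0
        by = cy + (frac - 0.5) * 0.9 * size * np.sin(angle)
        bx = cx + (frac - 0.5) * 0.9 * size * np.cos(angle)
        branch_angle = angle + (1 if k % 2 else -1) * rng.uniform(0.6, 1.1)
        tb = np.linspace(0, 0.25 * size, n_pts // 4)
        vy = np.clip(np.rint(by + tb * np.sin(branch_angle)), 0, size - 1).astype(int)
        vx = np.clip(np.rint(bx + tb * np.cos(branch_angle)), 0, size - 1).astype(int)
        selb = mask[vy, vx]
        img[vy[selb], vx[selb]] = vein_color


def _motif_aphid(rng, img, mask, dist_edge, radius, mi, size):
    # curl: concentric bright/dark ridges hugging the rim of the blade
    rim = (dist_edge > 0) & (dist_edge < 0.22 * radius)
    ridge = np.sin(dist_edge / max(1.0, 0.035 * radius) * np.pi)
    gain = 1.0 + mi * 0.35 * ridge
    img[rim] = np.clip(img[rim] * gain[rim][:, None], 0, 255)
    # aphid colonies: clusters of small white/black dots
    dot_r = max(1, int(round(size * 0.008)))
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return
    n_clusters = int(rng.integers(2, 5))
    for _ in range(n_clusters):
        j = rng.integers(len(ys))
        cy, cx = ys[j], xs[j]
        n_dots = int(round(rng.integers(10, 26) * mi))
        spread = 0.12 * radius
        for _ in range(n_dots):
            dy, dx = rng.normal(0, spread, 2)
            py, px = int(cy + dy), int(cx + dx)
            if 0 <= py < size and 0 <= px < size and mask[py, px]:
                shade = (rng.uniform(215, 245) if rng.random() < 0.6
                         else rng.uniform(12, 38))
                color = np.array([shade, shade, shade]) + rng.uniform(-8, 8, 3)
                _paint_disk(img, py, px, dot_r, np.clip(color, 0, 255))


def _motif_mite(rng, img, mask, dist_edge, radius, mi, size):
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return
    # yellow-white stipples over the blade
    n_stipple = int(round(mi * 90))
    dot_r = max(1, int(round(size * 0.006)))
    for _ in range(n_stipple):
        j = rng.integers(len(ys))
        color = np.array([225.0, 215.0, 135.0]) + rng.uniform(-15, 15, 3)
        _paint_disk(img, int(ys[j]), int(xs[j]), dot_r, np.clip(color, 0, 255))
    # reddening patch, area scaling with motif intensity
    j = rng.integers(len(ys))
    patch_r = (0.25 + 0.35 * mi) * radius
    yy, xx = _coords(size)
    d = np.hypot(yy - ys[j], xx - xs[j])
    fall = np.clip(1.0 - d / patch_r, 0.0, 1.0) ** 0.7
    w = (mi * fall * mask)[..., None]
    red = np.array([168.0, 62.0, 40.0]) + rng.uniform(-10, 10, 3)
    img[:] = (1 - w) * img + w * red


def _motif_mirid(rng, img, mask, dist_edge, radius, mi, size):
    ys, xs = np.nonzero(mask & (dist_edge > 0.1 * radius))
    if len(ys) == 0:
        return
    # black feeding spots
    n_spots = int(rng.integers(3, 9))
    dot_r = max(1, int(round(size * 0.01)))
    for _ in range(n_spots):
        j = rng.integers(len(ys))
        color = np.array([22.0, 18.0, 16.0]) + rng.uniform(0, 12, 3)
        _paint_disk(img, int(ys[j]), int(xs[j]), dot_r, color)
    # ragged holes with necrotic rims ("broken leaf")
    n_holes = int(round(rng.integers(2, 6) * mi))
    for _ in range(n_holes):
        j = rng.integers(len(ys))
        hole_r = rng.uniform(0.08, 0.16) * radius * (0.4 + 0.6 * mi)
        hole = _blob_mask(rng, size, float(ys[j]), float(xs[j]), hole_r,
                          wobble=0.5, n_harm=6) & mask
        rim = ndimage.binary_dilation(hole, iterations=max(1, int(size * 0.006))) & mask
        img[rim] = 0.45 * img[rim] + 0.55 * np.array([92.0, 66.0, 34.0])
        mask[hole] = False
        img[hole] = np.nan  # re-filled with background by the caller


def generate_leaf_image(label: str, rng: np.random.Generator,
                        cfg: SynthConfig) -> np.ndarray:
    """Render one labelled leaf image as a uint8 HxWx3 array."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASS_LABELS}")
    size = cfg.image_size
    bg = _render_background(rng, size, cfg.clutter_level)
    img = bg.copy()
    mask, dist_edge, centre, radius = _leaf_geometry(rng, size)
    _paint_leaf(rng, img, mask, dist_edge, centre)
    mi = cfg.motif_intensity
    if mi > 0:
        motif = {"aphid": _motif_aphid, "mite": _motif_mite,
                 "mirid": _motif_mirid}[label]
        motif(rng, img, mask, dist_edge, radius, mi, size)
        holes = np.isnan(img[..., 0])
        img[holes] = bg[holes]
    # sensor grain
    img += rng.normal(0.0, 2.5, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(cfg: SynthConfig, out_dir) -> "pd.DataFrame":  # noqa: F821
    """Write a class-per-directory synthetic dataset plus its manifest CSV."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists():
        raise FileExistsError(
            f"{manifest_path} already exists; remove it or use a fresh directory")
    records = []
    for class_idx, (label, count) in enumerate(zip(CLASS_LABELS, cfg.per_class_counts)):
        dest = out_dir / label
        if count:
            dest.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            rng = np.random.default_rng([cfg.seed, class_idx, i])
            img = generate_leaf_image(label, rng, cfg)
            image_id = f"{label}_{i:05d}"
            path = dest / f"{image_id}.png"
            write_image(img, path)
            records.append(dict(image_id=image_id, path=str(path), label=label,
                                split="unassigned", source_id=image_id,
                                transform="original"))
    manifest = new_manifest(records)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_manifest(manifest, manifest_path)
    return manifest
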