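"""Dataset manifests: construction, 7:2:1 splitting, augmentation bookkeeping.

A manifest is a :class:`pandas.DataFrame` with one row per image and columns
``image_id, path, label, split, source_id, transform``.  Original images
carry ``transform == "original"`` and ``source_id == image_id``; augmented
copies point back at their source and inherit its label and split, so a
split-then-augment pipeline can never leak an augmented view of a training
image into validation or test.

Splitting is per class.  When explicit per-class counts are given (the
published partition of 2705 field images does not follow any single
rounding rule) they are used verbatim; otherwise counts follow the largest
remainder method with ties resolved toward the earlier split.  Which images
land in which split is a seeded uniform shuffle within each class.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import DEFAULT_AUGMENTS, AugmentOp, apply_augment, read_image, write_image

__all__ = [
    "MANIFEST_COLUMNS",
    "CLASS_LABELS",
    "TABLE1_COUNTS",
    "SplitSpec",
    "new_manifest",
    "manifest_from_directory",
    "load_manifest",
    "save_manifest",
    "split_manifest",
    "augment_manifest",
    "summarize",
]

MANIFEST_COLUMNS = ("image_id", "path", "label", "split", "source_id", "transform")
SPLITS = ("train", "val", "test")
CLASS_LABELS = ("aphid", "mite", "mirid")

#: The published per-class (train, val, test) partition of the field dataset.
TABLE1_COUNTS: dict[str, tuple[int, int, int]] = {
    "aphid": (779, 222, 111),
    "mite": (493, 140, 70),
    "mirid": (624, 177, 89),
}


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    explicit_counts: Mapping[str, tuple[int, int, int]] | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r < 0 for r in self.ratios):
            raise ValueError("split ratios must be nonnegative")


def new_manifest(records: Sequence[dict] = ()) -> pd.DataFrame:
    df = pd.DataFrame(list(records), columns=list(MANIFEST_COLUMNS))
    return df.astype({c: "string" for c in MANIFEST_COLUMNS})


def manifest_from_directory(root) -> pd.DataFrame:
    """Import a class-per-directory layout ``root/<label>/<file>``."""
    root = Path(root)
    records = []
    for label_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(label_dir.iterdir()):
            if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                records.append(dict(image_id=f.stem, path=str(f), label=label_dir.name,
                                    split="unassigned", source_id=f.stem,
                                    transform="original"))
    return new_manifest(records)


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype="string")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df[list(MANIFEST_COLUMNS)]


def save_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _largest_remainder(total: int, ratios: Sequence[float]) -> list[int]:
    """Integer apportionment: floors plus largest fractional remainders,
    ties resolved toward the earlier split."""
    exact = [total * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = total - sum(base)
    # sort by descending remainder, then ascending position (stable tie-break)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_manifest(manifest: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Assign every original record to train/val/test, per class."""
    df = manifest.copy()
    if len(df) and not (df["split"] == "unassigned").all():
        raise ValueError("split_manifest expects all records unassigned")
    if len(df) and (df["transform"] != "original").any():
        raise ValueError("split_manifest operates on original records only")
    rng = np.random.default_rng(spec.seed)
    for label in sorted(df["label"].dropna().unique()):
        idx = df.index[df["label"] == label].to_numpy()
        n = len(idx)
        if spec.explicit_counts is not None and label in spec.explicit_counts:
            counts = list(spec.explicit_counts[label])
            if sum(counts) != n:
                raise ValueError(
                    f"explicit counts {counts} do not sum to class total {n} for {label!r}")
        else:
            counts = _largest_remainder(n, spec.ratios)
        perm = rng.permutation(n)
        bounds = np.cumsum([0] + counts)
        for split, lo, hi in zip(SPLITS, bounds[:-1], bounds[1:]):
            df.loc[idx[perm[lo:hi]], "split"] = split
    return df


def augment_manifest(manifest: pd.DataFrame,
                     ops: Sequence[AugmentOp] = DEFAULT_AUGMENTS,
                     keep_original: bool = False,
                     out_dir=None,
                     materialize: bool = True) -> pd.DataFrame:
    """Expand a split manifest: one derived record per (original, op).

    With ``materialize=True`` (default) each transformed image is written
    under ``out_dir/<label>/``; with ``materialize=False`` only the records
    are produced (the bookkeeping is identical).
    """
    df = manifest
    if len(df) and (df["split"] == "unassigned").any():
        raise ValueError("augment_manifest requires every record to carry a split; "
                         "split first to avoid train/test leakage")
    if materialize and len(df):
        if out_dir is None:
            raise ValueError("materialize=True requires out_dir")
        out_dir = Path(out_dir)
    records = []
    if keep_original:
        records.extend(df.to_dict("records"))
    for row in df.itertuples(index=False):
        img = read_image(row.path) if materialize else None
        for op in ops:
            new_id = f"{row.image_id}_{op.name}"
            if materialize:
                dest = out_dir / str(row.label)
                os.makedirs(dest, exist_ok=True)
                new_path = dest / f"{new_id}.png"
                write_image(apply_augment(img, op), new_path)
            else:
                new_path = f"{row.path}#{op.name}"
            records.append(dict(image_id=new_id, path=str(new_path), label=row.label,
                                split=row.split, source_id=row.image_id,
                                transform=op.name))
    return new_manifest(records)


def summarize(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-class x per-split count table with 'Total' margins."""
    if len(manifest) == 0:
        return pd.DataFrame(0, index=pd.Index(["Total"], name="label"),
                            columns=list(SPLITS) + ["Total"])
    table = pd.crosstab(manifest["label"], manifest["split"])
    for split in SPLITS:
        if split not in table.columns:
            table[split] = 0
    extra = [c for c in table.columns if c not in SPLITS]
    table = table[list(SPLITS) + extra]
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "label"
    return table.astype(int)
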