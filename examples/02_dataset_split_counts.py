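"""Dataset bookkeeping: per-class 7:2:1 split and sixfold augmentation.

Reproduces the arithmetic of the published partition tables: 2705 field
images (1112 aphid / 703 mite / 890 mirid) split per class with the
published counts, then expanded by the six augmentation transforms to
16,230 images.  Records only (no pixels) - the bookkeeping is identical.
"""

from resswin import TABLE1_COUNTS, SplitSpec, augment_manifest, split_manifest, summarize
from resswin.dataset import new_manifest

# build an unassigned manifest with the field per-class counts

records = []
for label, n in {"aphid": 1112, "mite": 703, "mirid": 890}.items():
    for i in range(n):
        iid = f"{label}_{i:05d}"
        records.append(dict(image_id=iid, path=f"data/{label}/{iid}.png",
                            label=label, split="unassigned", source_id=iid,
                            transform="original"))
manifest = new_manifest(records)

manifest = split_manifest(manifest, SplitSpec(explicit_counts=TABLE1_COUNTS, seed=42))
print("original partition:")
print(summarize(manifest), "\n")

augmented = augment_manifest(manifest, materialize=False)
print("after sixfold augmentation:")
print(summarize(augmented))
# every cell is exactly 6x its original counterpart; the train total is
# 11,376 and the grand total 16,230 images.
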