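"""Train the improved classifier on synthetic leaf images at desk scale.

Generates 75 labelled 56-px synthetic images (25 per class), splits them
80/10/10, trains a reduced improved model (two stages, 32 embedding
channels) for 30 epochs with Adam at learning rate 0.001, and evaluates
precision/recall/specificity/F1 and accuracy on the held-out split.
Runs in a few minutes on one CPU core.
"""

import tempfile
from pathlib import Path

from resswin import (ImprovedModelConfig, ResidualSwinClassifier, SplitSpec,
                     SwinConfig, TrainConfig, evaluate, generate_dataset,
                     split_manifest, train)
from resswin.synthgen import SynthConfig

root = Path(tempfile.mkdtemp(prefix="resswin_demo_"))
cfg = SynthConfig(per_class_counts=(25, 25, 25), image_size=56, seed=11)
manifest = split_manifest(generate_dataset(cfg, root),
                          SplitSpec(ratios=(0.8, 0.1, 0.1), seed=0))

small = SwinConfig(img_size=56, embed_dim=32, depths=(2, 2), num_heads=(2, 4))
model = ResidualSwinClassifier(ImprovedModelConfig(backbone=small), backbone_seed=3)

history, best = train(model, manifest, TrainConfig(epochs=30, batch_size=15, seed=1))
for h in history[::5] + [history[-1]]:
    print(f"epoch {h['epoch']:>2}: train loss {h['train_loss']:.3f} "
          f"acc {h['train_accuracy']:.2f} | val loss {h['val_loss']:.3f} "
          f"acc {h['val_accuracy']:.2f}")
print(f"\nbest checkpoint: epoch {best.epoch} (val acc {best.val_accuracy:.2f})")

report, cm = evaluate(model, manifest, "test")
print("\nheld-out metrics:")
print(report.format_table())
print("\nconfusion matrix (rows true, columns predicted):")
print(cm.counts)
# the motifs carry the class signal, so a correctly wired model overfits 60
# training images and separates the held-out set almost perfectly.
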