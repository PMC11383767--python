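"""Training, evaluation, prediction and Grad-CAM explanation.

Training follows the published protocol: Adam at learning rate 0.001,
cross-entropy loss, up to 100 epochs, with the model checkpointed every
epoch and the best checkpoint chosen by highest validation accuracy (ties
broken by lower validation loss, then earlier epoch).  Batch size and the
absence of weight decay / LR scheduling are package defaults; everything is
seeded and deterministic on fixed hardware.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .imaging import read_image, resize_bicubic
from .metrics import ConfusionMatrix, MetricsReport, confusion_matrix, metrics_report
from .nn import Adam, Module
from .swin import SwinConfig, normalize_image

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "class_order",
    "train",
    "evaluate",
    "predict",
    "grad_cam",
    "select_best_epoch",
    "cross_entropy",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class Checkpoint:
    epoch: int  # 1-based
    weights: dict[str, np.ndarray]
    val_accuracy: float
    val_loss: float


def class_order(manifest: pd.DataFrame) -> list[str]:
    """Class labels in order of first appearance in the manifest."""
    return list(dict.fromkeys(manifest["label"].tolist()))


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets under softmax logits."""
    logp = ad.log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(targets)), np.asarray(targets, dtype=np.int64)]
    return -picked.mean()


def _load_split(manifest: pd.DataFrame, split: str, model_cfg: SwinConfig,
                classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    rows = manifest[manifest["split"] == split]
    if len(rows) == 0:
        raise ValueError(f"manifest has no records in split {split!r}")
    size = model_cfg.img_size
    images, labels = [], []
    errors = []
    for row in rows.itertuples(index=False):
        try:
            img = read_image(row.path)
        except OSError as exc:
            errors.append(f"{row.path}: {exc}")
            continue
        if img.shape[:2] != (size, size):
            img = resize_bicubic(img, size, size)
        images.append(normalize_image(img, model_cfg))
        labels.append(classes.index(row.label))
    if errors:
        raise FileNotFoundError("unreadable images:\n" + "\n".join(errors))
    return np.stack(images).astype(np.float32), np.asarray(labels, dtype=np.int64)


def _forward_eval(model: Module, images: np.ndarray, labels: np.ndarray,
                  batch_size: int) -> tuple[float, float, np.ndarray]:
    """(mean loss, accuracy, predictions) without touching the weights."""
    was_training = model.training
    model.eval()
    losses, preds = [], []
    for lo in range(0, len(images), batch_size):
        batch = images[lo:lo + batch_size]
        logits = model(Tensor(batch))
        losses.append(cross_entropy(logits, labels[lo:lo + batch_size]).item()
                      * len(batch))
        preds.append(np.argmax(logits.data, axis=-1))
    if was_training:
        model.train()
    preds = np.concatenate(preds)
    return float(np.sum(losses) / len(images)), float(np.mean(preds == labels)), preds


def select_best_epoch(history: list[dict]) -> int:
    """Index of the best epoch: max val accuracy, then min val loss, then earliest."""
    return min(range(len(history)),
               key=lambda i: (-history[i]["val_accuracy"], history[i]["val_loss"], i))


def train(model: Module, manifest: pd.DataFrame, cfg: TrainConfig,
          checkpoint_dir=None, log_path=None
          ) -> tuple[list[dict], Checkpoint]:
    """Train ``model`` on the manifest's train split, validating every epoch.

    Returns the per-epoch history and the best checkpoint (weights copied).
    """
    classes = class_order(manifest)
    model_cfg: SwinConfig = getattr(model, "cfg", None)
    if hasattr(model_cfg, "backbone"):
        model_cfg = model_cfg.backbone
    train_x, train_y = _load_split(manifest, "train", model_cfg, classes)
    val_x, val_y = _load_split(manifest, "val", model_cfg, classes)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best: Checkpoint | None = None
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(train_x))
        ep_loss, ep_correct = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = model(Tensor(train_x[idx]))
            loss = cross_entropy(logits, train_y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(idx)
            ep_correct += int(np.sum(np.argmax(logits.data, axis=-1) == train_y[idx]))
        val_loss, val_acc, _ = _forward_eval(model, val_x, val_y, cfg.batch_size)
        entry = dict(epoch=epoch,
                     train_loss=ep_loss / len(train_x),
                     train_accuracy=ep_correct / len(train_x),
                     val_loss=val_loss, val_accuracy=val_acc)
        history.append(entry)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        if checkpoint_dir is not None:
            np.savez(f"{checkpoint_dir}/epoch_{epoch:03d}.npz", **model.state_dict())
        if (best is None or val_acc > best.val_accuracy
                or (val_acc == best.val_accuracy and val_loss < best.val_loss)):
            best = Checkpoint(epoch=epoch, weights=model.state_dict(),
                              val_accuracy=val_acc, val_loss=val_loss)
    return history, best


def evaluate(model: Module, manifest: pd.DataFrame, split: str = "test",
             batch_size: int = 32, specificity_denominator: str = "fp"
             ) -> tuple[MetricsReport, ConfusionMatrix]:
    """Inference on one split (no augmentation applied at evaluation time)."""
    classes = class_order(manifest)
    model_cfg = getattr(model, "cfg", None)
    if hasattr(model_cfg, "backbone"):
        model_cfg = model_cfg.backbone
    images, labels = _load_split(manifest, split, model_cfg, classes)
    _, _, preds = _forward_eval(model, images, labels, batch_size)
    cm = confusion_matrix(labels, preds, len(classes), tuple(classes))
    return metrics_report(cm, specificity_denominator), cm


def predict(model: Module, image_path, classes: list[str] | None = None
            ) -> tuple[str | int, np.ndarray, float]:
    """(predicted label, class probabilities, wall-clock latency in seconds)."""
    model_cfg = getattr(model, "cfg", None)
    if hasattr(model_cfg, "backbone"):
        model_cfg = model_cfg.backbone
    img = read_image(image_path)
    size = model_cfg.img_size
    if img.shape[:2] != (size, size):
        img = resize_bicubic(img, size, size)
    x = normalize_image(img, model_cfg)[None]
    model.eval()
    start = time.perf_counter()
    logits = model(Tensor(x.astype(np.float32)))
    probs = ad.softmax(logits, axis=-1).data[0]
    latency = time.perf_counter() - start
    k = int(np.argmax(probs))
    label = classes[k] if classes is not None else k
    return label, probs, latency


def _default_cam_layer(model: Module) -> str:
    n = len(getattr(model, "backbone", model).stages)
    cache = model.cache
    name = f"stage{n}_module2_input"
    return name if name in cache else f"stage{n}_output"


def grad_cam(model: Module, image: np.ndarray, target_class: int,
             target_layer: str | None = None,
             channels_first: bool | None = None) -> np.ndarray:
    """Gradient-weighted class activation map, in [0, 1], at input resolution.

    The target layer must be a cached spatial feature of the forward pass
    (default: the input to the last stage's residual module 2 when present,
    else the last stage's token grid).  Channel-averaged gradients weight
    the activations; the weighted sum is rectified, min-max normalised and
    bilinearly upsampled to the input size.
    """
    model_cfg = getattr(model, "cfg", None)
    if hasattr(model_cfg, "backbone"):
        model_cfg = model_cfg.backbone
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("grad_cam expects one HxWx3 image")
    if img.dtype == np.uint8:
        size = model_cfg.img_size
        if img.shape[:2] != (size, size):
            img = resize_bicubic(img, size, size)
        img = normalize_image(img, model_cfg)
    model.eval()
    logits = model(Tensor(img[None].astype(np.float32)))
    model.zero_grad()
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    logits.backward(onehot)
    layer = target_layer or _default_cam_layer(model)
    if layer not in model.cache:
        raise ValueError(f"no cached activation named {layer!r}; "
                         f"available: {sorted(model.cache)}")
    act_t = model.cache[layer]
    if act_t.grad is None:
        raise ValueError(f"layer {layer!r} received no gradient")
    act, grad = act_t.data[0], act_t.grad[0]
    if act.ndim != 3:
        raise ValueError("target layer must produce a spatial feature map")
    if channels_first is None:
        # module-2 inputs are cached as (C, h, w); token grids as (h, w, C)
        channels_first = layer.endswith("module2_input")
    if not channels_first:
        act, grad = act.transpose(2, 0, 1), grad.transpose(2, 0, 1)
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    if cam.max() <= 0.0:
        cam = np.zeros_like(cam)
    else:
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    zoom = (img.shape[0] / cam.shape[0], img.shape[1] / cam.shape[1])
    return np.clip(ndimage.zoom(cam, zoom, order=1), 0.0, 1.0)


def export_history(history: list[dict], csv_path=None, png_path=None) -> None:
    """Write the per-epoch accuracy/loss curves as CSV and/or a PNG figure."""
    df = pd.DataFrame(history)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, (ax_a, ax_l) = plt.subplots(1, 2, figsize=(9, 3.5))
        for key in ("train_accuracy", "val_accuracy"):
            ax_a.plot(df["epoch"], df[key], label=key)
        for key in ("train_loss", "val_loss"):
            ax_l.plot(df["epoch"], df[key], label=key)
        ax_a.set_xlabel("epoch"), ax_a.set_ylabel("accuracy"), ax_a.legend()
        ax_l.set_xlabel("epoch"), ax_l.set_ylabel("loss"), ax_l.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def render_cam_overlay(image: np.ndarray, cam: np.ndarray, path) -> None:
    """Save the heatmap blended over the image (matplotlib 'jet' colouring)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.cm as mpl_cm
    from .imaging import write_image
    heat = (mpl_cm.jet(cam)[..., :3] * 255).astype(np.float64)
    base = np.asarray(image, dtype=np.float64)
    if base.shape[:2] != cam.shape:
        base = resize_bicubic(base.astype(np.uint8), *cam.shape).astype(np.float64)
    write_image(np.clip(0.55 * base + 0.45 * heat, 0, 255).astype(np.uint8), path)
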