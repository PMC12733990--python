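"""Training loops, learning-rate schedule, checkpoints and cascade inference."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .clsnet import ClsNet, ClsNetConfig
from .cls_losses import TERM_NAMES, AdaptiveWeights, adaptive_weights, compound_cls_loss
from .metrics import mean_foreground_dice, seg_metrics
from .nn.tensor import Tensor
from .phantom import LabeledVolume
from .preprocess import PreprocessConfig, hu_window, normalize_three_stage, pad_to_multiple, resample, unpad
from .roi import ROIConfig, roi_pipeline
from .seg_losses import SegLossWeights, compound_seg_loss, make_boundary_maps
from .segnet import SegNet, SegNetConfig, init_weights

__all__ = [
    "StageConfig",
    "TrainConfig",
    "lr_schedule",
    "train_seg",
    "train_cls",
    "cascade_infer",
    "prepare_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class StageConfig:
    epochs: int
    lr: float
    batch: int


@dataclass(frozen=True)
class TrainConfig:
    seg: StageConfig = StageConfig(epochs=100, lr=1e-4, batch=4)
    cls: StageConfig = StageConfig(epochs=50, lr=5e-5, batch=16)
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    grad_clip_norm: float = 1.0
    warmup_epochs: int = 5
    warmup_start_lr: float = 1e-6
    floor_lr: float = 1e-7
    split_seed: int = 42
    model_seed: int = 123
    dtype: str = "float32"  # training precision; inference matches

    def __post_init__(self):
        for stage in (self.seg, self.cls):
            if min(stage.epochs, stage.batch) < 1 or stage.lr <= 0:
                raise ValueError("epochs, batch and lr must be positive")
        if self.warmup_epochs >= max(self.seg.epochs, self.cls.epochs):
            raise ValueError("warmup must be shorter than the longest stage")

    @staticmethod
    def desk() -> "TrainConfig":
        """CPU-scale smoke protocol: few epochs, larger step size, warmup 1."""
        return TrainConfig(
            seg=StageConfig(epochs=5, lr=3e-3, batch=8),
            cls=StageConfig(epochs=10, lr=3e-3, batch=8),
            warmup_epochs=1,
        )


def lr_schedule(step: int, total_steps: int, warmup_steps: int, base_lr: float,
                start_lr: float = 1e-6, floor_lr: float = 1e-7) -> float:
    """Linear warmup from ``start_lr`` to ``base_lr``, then cosine decay to
    ``floor_lr``; continuous at the warmup/cosine joint."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if warmup_steps > 0 and step < warmup_steps:
        t = step / warmup_steps
        return start_lr + t * (base_lr - start_lr)
    span = max(1, total_steps - warmup_steps)
    t = min(1.0, (step - warmup_steps) / span)
    return floor_lr + 0.5 * (base_lr - floor_lr) * (1.0 + np.cos(np.pi * t))


@dataclass
class PreparedVolume:
    """Network-ready tensors for one patient."""

    seg_input: np.ndarray  # 3-stage-normalized, padded, (D, H, W)
    windowed: np.ndarray  # [0, 1] windowed intensities, padded (ROI source)
    mask: np.ndarray  # padded labels
    onehot: np.ndarray  # (5, D, H, W)
    boundary_maps: tuple  # cached make_boundary_maps output for (1, 5, ...)
    pad_record: tuple
    spacing: tuple
    patient_id: str
    lesion_class: str


def prepare_volume(v: LabeledVolume, cfg: PreprocessConfig = PreprocessConfig(),
                   sdt_sigma: float = 1.5, dtype=np.float32) -> PreparedVolume:
    """Full preprocessing protocol plus cached training targets."""
    v = resample(v, cfg)
    win = hu_window(v.image, cfg)
    norm = normalize_three_stage(win, v.mask == 1, patch_size=cfg.patch_size)
    norm, rec = pad_to_multiple(norm, cfg.pad_multiple)
    win_p, _ = pad_to_multiple(win, cfg.pad_multiple)
    mask_p, _ = pad_to_multiple(v.mask, cfg.pad_multiple)
    onehot = np.moveaxis(np.eye(5, dtype=dtype)[mask_p], -1, 0)
    maps = make_boundary_maps(onehot[None], sigma=sdt_sigma, force_all=True)
    return PreparedVolume(
        seg_input=norm.astype(dtype),
        windowed=win_p.astype(dtype),
        mask=mask_p,
        onehot=onehot,
        boundary_maps=maps,
        pad_record=rec,
        spacing=v.spacing_mm,
        patient_id=v.patient_id,
        lesion_class=v.patient_class,
    )


def _write_log(log_path, record):
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps(record, default=float) + "\n")


def _stack_batch(items: list[PreparedVolume]):
    x = np.stack([it.seg_input for it in items])[:, None]
    y = np.stack([it.onehot for it in items])
    d = np.concatenate([it.boundary_maps[0] for it in items], axis=0)
    sel = np.stack([it.boundary_maps[1] for it in items]).max(axis=0)
    return x, y, (d, sel)


def _epoch_losses(net: SegNet, items, weights, batch):
    """Mean compound loss over a dataset in evaluation mode."""
    net.eval()
    total, n = 0.0, 0
    for i in range(0, len(items), batch):
        x, y, maps = _stack_batch(items[i : i + batch])
        logits = net.forward_tensor(Tensor(x))
        loss, _ = compound_seg_loss(logits.softmax(axis=1), y, weights, boundary_maps=maps)
        total += loss.item() * len(y)
        n += len(y)
    return total / max(1, n)


def train_seg(train_items: list[PreparedVolume], cfg: TrainConfig,
              net_cfg: SegNetConfig = SegNetConfig(), val_items=(),
              loss_weights: SegLossWeights = SegLossWeights(), log_path=None):
    """Train the segmenter; returns (net, log, best_state)."""
    if not train_items:
        raise ValueError("training set must be nonempty")
    dtype = np.float32 if cfg.dtype == "float32" else np.float64
    net = init_weights(SegNet(net_cfg), cfg.model_seed).astype(dtype)
    net.dropout.seed(cfg.model_seed)
    opt = nn.AdamW(net.parameters(), lr=cfg.seg.lr, betas=cfg.betas, eps=cfg.eps,
                   weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.model_seed)
    stage = cfg.seg
    steps_per_epoch = int(np.ceil(len(train_items) / stage.batch))
    total_steps = stage.epochs * steps_per_epoch
    warmup_steps = cfg.warmup_epochs * steps_per_epoch
    log, best = [], {"val_loss": np.inf, "state": None, "epoch": -1}
    step = 0
    for epoch in range(stage.epochs):
        net.train()
        order = rng.permutation(len(train_items))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), stage.batch):
            batch = [train_items[j] for j in order[i : i + stage.batch]]
            x, y, maps = _stack_batch(batch)
            opt.lr = lr_schedule(step, total_steps, warmup_steps, stage.lr,
                                 cfg.warmup_start_lr, cfg.floor_lr)
            logits = net.forward_tensor(Tensor(x))
            loss, terms = compound_seg_loss(logits.softmax(axis=1), y, loss_weights,
                                            boundary_maps=maps)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"segmentation training diverged at epoch {epoch} step {step}: "
                    f"loss={loss.item()} terms={terms}"
                )
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(net.parameters(), cfg.grad_clip_norm)
            opt.step()
            epoch_loss += loss.item() * len(batch)
            seen += len(batch)
            step += 1
        record = {"stage": "seg", "epoch": epoch, "lr": opt.lr,
                  "train_loss": epoch_loss / seen}
        if val_items:
            record["val_loss"] = _epoch_losses(net, list(val_items), loss_weights, stage.batch)
            record["val_dice"] = float(np.mean([
                mean_foreground_dice(seg_metrics(
                    net(it.seg_input).probs[0].argmax(axis=0), it.mask, it.spacing))
                for it in val_items
            ]))
            if record["val_dice"] > best.get("val_dice", -1.0):
                best = {"val_loss": record["val_loss"], "val_dice": record["val_dice"],
                        "state": net.state_dict(), "epoch": epoch}
        log.append(record)
        _write_log(log_path, record)
    if best["state"] is None:
        best = {"val_loss": log[-1]["train_loss"], "state": net.state_dict(),
                "epoch": stage.epochs - 1}
    net.eval()
    return net, log, best


def train_cls(rois: list[tuple[np.ndarray, int, float]], cfg: TrainConfig,
              net_cfg: ClsNetConfig = ClsNetConfig(), val_rois=(), log_path=None,
              sampler: str = "stratified"):
    """Train the ROI classifier with per-epoch adaptive loss weights.

    ``rois``: (patch, label index, confidence S) triples.
    Returns (net, log, best_state).
    """
    if not rois:
        raise ValueError("ROI set must be nonempty")
    dtype = np.float32 if cfg.dtype == "float32" else np.float64
    net = init_weights(ClsNet(net_cfg), cfg.model_seed).astype(dtype)
    for m in net.modules():
        if isinstance(m, nn.Dropout):
            m.seed(cfg.model_seed)
    opt = nn.AdamW(net.parameters(), lr=cfg.cls.lr, betas=cfg.betas, eps=cfg.eps,
                   weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.model_seed + 1)
    stage = cfg.cls
    patches = np.stack([r[0] for r in rois]).astype(dtype)
    labels = np.array([r[1] for r in rois], dtype=int)
    svals = np.array([r[2] for r in rois], dtype=float)
    steps_per_epoch = int(np.ceil(len(rois) / stage.batch))
    total_steps = stage.epochs * steps_per_epoch
    warmup_steps = cfg.warmup_epochs * steps_per_epoch
    weights = AdaptiveWeights()
    history = {name: [] for name in TERM_NAMES}
    log, best = [], {"val_loss": np.inf, "state": None, "epoch": -1}
    step = 0
    for epoch in range(stage.epochs):
        net.train()
        order = _epoch_order(labels, rng, sampler)
        epoch_terms = {name: 0.0 for name in TERM_NAMES}
        epoch_loss, seen, correct = 0.0, 0, 0
        for i in range(0, len(order), stage.batch):
            idx = order[i : i + stage.batch]
            opt.lr = lr_schedule(step, total_steps, warmup_steps, stage.lr,
                                 cfg.warmup_start_lr, cfg.floor_lr)
            alpha = net.forward_tensor(patches[idx], svals[idx])
            loss, terms = compound_cls_loss(alpha, labels[idx], svals[idx], weights)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"classifier training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(net.parameters(), cfg.grad_clip_norm)
            opt.step()
            for name in TERM_NAMES:
                epoch_terms[name] += terms[name] * len(idx)
            epoch_loss += loss.item() * len(idx)
            correct += int((alpha.data.argmax(axis=1) == labels[idx]).sum())
            seen += len(idx)
            step += 1
        for name in TERM_NAMES:
            history[name].append(epoch_terms[name] / seen)
        weights = adaptive_weights(history, weights)
        record = {
            "stage": "cls", "epoch": epoch, "lr": opt.lr,
            "train_loss": epoch_loss / seen, "train_acc": correct / seen,
            "lambdas": [float(x) for x in weights.lambdas],
            "z": [float(x) for x in weights.z],
        }
        if val_rois:
            vp = np.stack([r[0] for r in val_rois]).astype(dtype)
            vl = np.array([r[1] for r in val_rois])
            vs = np.array([r[2] for r in val_rois])
            net.eval()
            va = net.forward_tensor(vp, vs)
            vloss, _ = compound_cls_loss(va, vl, vs, weights)
            record["val_loss"] = vloss.item()
            record["val_acc"] = float((va.data.argmax(axis=1) == vl).mean())
            better_acc = record["val_acc"] > best.get("val_acc", -1.0)
            tie_better_loss = (record["val_acc"] == best.get("val_acc", -1.0)
                               and record["val_loss"] < best["val_loss"])
            if better_acc or tie_better_loss:
                best = {"val_loss": record["val_loss"], "val_acc": record["val_acc"],
                        "state": net.state_dict(), "epoch": epoch}
        log.append(record)
        _write_log(log_path, record)
    if best["state"] is None:
        best = {"val_loss": log[-1]["train_loss"], "state": net.state_dict(),
                "epoch": stage.epochs - 1}
    net.eval()
    return net, log, best


def _epoch_order(labels: np.ndarray, rng, mode) -> np.ndarray:
    """Epoch sample order.

    ``mode``: False/None — plain shuffle; "stratified" / True — interleaved
    per-class shuffle so batches stay near class-proportional; "balanced" —
    classes drawn uniformly with replacement (epoch length unchanged), the
    standard oversampling remedy for rare-class starvation.
    """
    if not mode:
        return rng.permutation(len(labels))
    present = [c for c in range(4) if (labels == c).any()]
    if mode == "balanced":
        order = []
        for _ in range(len(labels)):
            c = present[rng.integers(len(present))]
            pool = np.flatnonzero(labels == c)
            order.append(pool[rng.integers(len(pool))])
        return np.array(order, dtype=int)
    buckets = [rng.permutation(np.flatnonzero(labels == c)) for c in range(4)]
    order = []
    while any(len(b) for b in buckets):
        for c in rng.permutation(4):
            if len(buckets[c]):
                order.append(buckets[c][0])
                buckets[c] = buckets[c][1:]
    return np.array(order, dtype=int)


# ----------------------------------------------------------------------
# cascade inference
# ----------------------------------------------------------------------

def mc_dropout_probs(net: SegNet, x: np.ndarray, n_passes: int, seed: int):
    """Stochastic forward passes with dropout active (image (D, H, W))."""
    passes = []
    net.train()
    for t in range(n_passes):
        net.dropout.seed(seed + t)
        passes.append(net(x).probs[0])
    net.eval()
    return passes


def cascade_infer(v: LabeledVolume, seg_net: SegNet, cls_net: ClsNet,
                  pre_cfg: PreprocessConfig = PreprocessConfig(),
                  roi_cfg: ROIConfig = ROIConfig(), n_mc_passes: int = 5,
                  mc_seed: int = 0, use_mask_norm: bool = True):
    """Preprocess -> segment -> extract ROIs -> classify each ROI.

    Returns (probs (5, D, H, W) on the unpadded grid, list of
    (ROIRecord, DirichletPrediction)).
    """
    vr = resample(v, pre_cfg)
    win = hu_window(vr.image, pre_cfg)
    kidney = (vr.mask == 1) if use_mask_norm else None
    norm = normalize_three_stage(win, kidney, patch_size=pre_cfg.patch_size)
    norm_p, rec = pad_to_multiple(norm, pre_cfg.pad_multiple)
    win_p, _ = pad_to_multiple(win, pre_cfg.pad_multiple)
    dtype = seg_net.parameters()[0].data.dtype
    seg_in = norm_p.astype(dtype)
    seg_net.eval()
    probs_p = seg_net(seg_in).probs[0]
    mc = mc_dropout_probs(seg_net, seg_in, n_mc_passes, mc_seed) if n_mc_passes > 1 else [probs_p]
    records = roi_pipeline(win_p, probs_p, v.patient_id, mc_probs=mc, cfg=roi_cfg)
    preds = []
    for r in records:
        preds.append(cls_net(r.patch.astype(dtype), r.confidence_S))
    probs = np.stack([unpad(probs_p[c], rec) for c in range(5)])
    return probs, list(zip(records, preds))


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, net: nn.Module, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {k: v for k, v in net.state_dict().items()}
    np.savez(path, **state)
    if config is not None:
        Path(str(path) + ".json").write_text(json.dumps(config, indent=2))


def load_checkpoint(path, net: nn.Module) -> nn.Module:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    net.load_state_dict({k: data[k] for k in data.files})
    return net
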