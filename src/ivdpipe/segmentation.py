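"""Multi-class U-Net slice segmentation with patient-level cross-validation.

Training respects patient boundaries: every slice of a patient lands in
exactly one of train/val/test per fold, so no subject leaks between
splits.  The network is a standard encoder–decoder U-Net (two 3x3
convolutions per level, 2x2 max pooling, nearest-neighbour upsampling
with skip concatenation) trained with an Adam optimizer on macro
soft-Dice loss, after a short class-rebalanced cross-entropy warm-up
that keeps thin structures alive when starting from random weights.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nn
from .phantom import CLASS_MAP, LabelVolume, VolumeStack

__all__ = [
    "FoldSplit",
    "SegModelConfig",
    "SegMetrics",
    "make_folds",
    "dice_loss",
    "UNet",
    "train_segmenter",
    "segment_volume",
    "segmentation_metrics",
]


# ---------------------------------------------------------------------------
# folds

@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    test_patients: tuple[str, ...]
    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]

    def __post_init__(self):
        groups = (set(self.test_patients), set(self.train_patients), set(self.val_patients))
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("fold splits must be pairwise disjoint")


def make_folds(
    patient_ids, k: int, val_fraction: float = 0.15, seed: int = 0
) -> list[FoldSplit]:
    """Patient-level k-fold splits with an inner train/val division.

    Patients are shuffled once, cut into k near-equal test folds, and the
    remainder of each fold is split (1 - val_fraction)/val_fraction into
    train/val.  Every patient appears in exactly one test set.
    """
    ids = sorted(set(patient_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available patients")
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    chunks = [list(c) for c in np.array_split(np.arange(len(order)), k)]
    folds = []
    for fi, chunk in enumerate(chunks):
        test = [order[i] for i in chunk]
        rest = [p for p in order if p not in set(test)]
        n_val = int(round(val_fraction * len(rest)))
        # reshuffle the remainder so val membership varies across folds
        rest = [rest[i] for i in rng.permutation(len(rest))]
        val, train = rest[:n_val], rest[n_val:]
        folds.append(FoldSplit(fi, tuple(test), tuple(train), tuple(val)))
    return folds


# ---------------------------------------------------------------------------
# loss

def dice_loss(predicted_probabilities, target, smooth: float = 1e-6,
              include_background: bool = False):
    """Macro soft-Dice loss, 1 - mean per-class soft Dice.

    ``predicted_probabilities`` is (N, C, H, W) summing to 1 over classes;
    ``target`` is an integer label array (N, H, W).  By default the mean
    runs over the foreground classes only; training includes the
    background term (``include_background=True``) because leaving the
    background class without gradient lets the optimizer park its
    probability mass on an arbitrary foreground class over background
    tissue and stall there.  Returns a Tensor when given a Tensor
    (differentiable), otherwise a float.
    """
    is_tensor = isinstance(predicted_probabilities, nn.Tensor)
    probs = predicted_probabilities if is_tensor else nn.Tensor(predicted_probabilities)
    target = np.asarray(target)
    n, c, h, w = probs.shape
    if target.shape != (n, h, w):
        raise ValueError("prediction and target shapes are incompatible")
    sums = probs.data.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-5:
        raise ValueError("probabilities must sum to 1 per pixel")
    onehot = np.zeros((n, c, h, w))
    for cls in range(c):
        onehot[:, cls] = target == cls
    onehot_t = nn.Tensor(onehot)
    inter = (probs * onehot_t).sum(axis=3).sum(axis=2).sum(axis=0)  # (C,)
    denom = probs.sum(axis=3).sum(axis=2).sum(axis=0) + nn.Tensor(onehot.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + smooth) * (denom + smooth) ** -1.0
    first = 0 if include_background else 1
    loss = 1.0 - dice.gather(np.arange(first, c)).mean()
    return loss if is_tensor else float(loss.data)


def _pixel_cross_entropy(probs, target):
    """Class-rebalanced per-pixel negative log-likelihood.

    Pixels are weighted by the inverse square root of their class's pixel
    count in the batch, so thin structures (discs) pull as hard as bulk
    ones; used as a warm-up objective that revives classes soft Dice
    alone starves when training from random initialization."""
    n, c, h, w = probs.shape
    counts = np.array([(target == cls).sum() for cls in range(c)], dtype=float)
    weights = np.where(counts > 0, 1.0 / np.sqrt(np.maximum(counts, 1.0)), 0.0)
    present = weights > 0
    weights[present] /= weights[present].mean()
    onehot = np.zeros((n, c, h, w))
    for cls in range(c):
        onehot[:, cls] = (target == cls) * weights[cls]
    total = onehot.sum()
    return -((probs + 1e-8).log() * nn.Tensor(onehot)).sum() * (1.0 / total)


# ---------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class SegModelConfig:
    base_features: int = 32
    n_classes: int = 12
    depth: int = 4
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    augmentation: bool = True
    max_rotation_deg: float = 10.0
    intensity_jitter: float = 0.1
    grad_clip: float = 5.0  # max global gradient norm; 0 disables
    lr_decay: float = 0.3  # learning-rate factor applied after 2/3 of epochs
    coord_channels: bool = True  # append normalized (row, col) input planes
    ce_warmup_epochs: int = 5  # cross-entropy epochs before switching to dice
    seed: int = 0

    def __post_init__(self):
        if self.base_features < 1 or self.depth < 1 or self.n_classes < 2:
            raise ValueError("invalid model size")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _DoubleConv(nn.Module):
    def __init__(self, c_in, c_out, rng):
        self.a = nn.Conv2d(c_in, c_out, 3, rng)
        self.b = nn.Conv2d(c_out, c_out, 3, rng)

    def forward(self, x):
        return self.b(self.a(x).relu()).relu()


class UNet(nn.Module):
    """Encoder–decoder segmentation network with skip connections.

    ``base_features`` filters at the top level, doubling at each of
    ``depth`` poolings; input spatial dims must be divisible by 2**depth.
    """

    def __init__(self, config: SegModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_features
        self.enc = []
        # normalized coordinate planes give the otherwise translation-blind
        # convolutions the cranio-caudal position cue that separates
        # visually identical structures at different spinal levels
        c_in = 3 if config.coord_channels else 1
        feats = [f * 2 ** d for d in range(config.depth + 1)]
        for c_out in feats[:-1]:
            self.enc.append(_DoubleConv(c_in, c_out, rng))
            c_in = c_out
        self.bottleneck = _DoubleConv(c_in, feats[-1], rng)
        self.up = []
        self.dec = []
        c_in = feats[-1]
        for c_out in reversed(feats[:-1]):
            self.up.append(nn.Conv2d(c_in, c_out, 1, rng))
            self.dec.append(_DoubleConv(2 * c_out, c_out, rng))
            c_in = c_out
        self.head = nn.Conv2d(c_in, config.n_classes, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(f"input spatial dims must be divisible by {div}")
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = x.maxpool2d()
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(x.upsample2d())
            x = dec(nn.concat([skip, x], axis=1))
        return self.head(x)

    def net_input(self, slices: np.ndarray) -> np.ndarray:
        """(N, C, H, W) network input for a (N, H, W) batch of slices."""
        n, h, w = slices.shape
        if not self.config.coord_channels:
            return slices[:, None]
        rr = np.broadcast_to(np.linspace(-1, 1, h)[None, :, None], (n, h, w))
        cc = np.broadcast_to(np.linspace(-1, 1, w)[None, None, :], (n, h, w))
        return np.stack([slices, rr, cc], axis=1)

    def predict_probabilities(self, slices: np.ndarray) -> np.ndarray:
        """Class probabilities for a (N, H, W) batch of intensity slices."""
        x = nn.Tensor(self.net_input(slices))
        return self.forward(x).log_softmax(axis=1).exp().data


# ---------------------------------------------------------------------------
# training

def _normalize_stack(stack: VolumeStack) -> np.ndarray:
    vol = stack.intensities
    peak = vol.max()
    return vol / peak if peak > 0 else vol


def _augment_slice(img, mask, config: SegModelConfig, rng):
    if rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
    mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
    img = img * (1.0 + rng.uniform(-config.intensity_jitter, config.intensity_jitter))
    return np.ascontiguousarray(np.clip(img, 0, None)), np.ascontiguousarray(mask)


def _collect_slices(data, patients):
    imgs, masks = [], []
    for pid in patients:
        stack, labels = data[pid]
        vol = _normalize_stack(stack)
        for s in range(vol.shape[0]):
            imgs.append(vol[s])
            masks.append(labels.labels[s])
    return np.asarray(imgs), np.asarray(masks)


def train_one(
    data: dict[str, tuple[VolumeStack, LabelVolume]],
    train_patients,
    val_patients,
    config: SegModelConfig,
) -> tuple[UNet, dict]:
    """Train a single U-Net on the given patients; returns model + history."""
    if not train_patients:
        raise ValueError("training set is empty")
    model = UNet(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    tr_imgs, tr_masks = _collect_slices(data, train_patients)
    val = _collect_slices(data, val_patients) if val_patients else None
    history = {"train_loss": [], "val_loss": []}
    best_state, best_val = model.state_dict(), np.inf
    for epoch in range(config.epochs):
        # step decay stabilizes the late phase of dice-loss optimization
        opt.lr = config.learning_rate * (
            config.lr_decay if epoch >= (2 * config.epochs) // 3 else 1.0
        )
        order = rng.permutation(len(tr_imgs))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            bi, bm = [], []
            for i in sel:
                img, mask = tr_imgs[i], tr_masks[i]
                if config.augmentation:
                    img, mask = _augment_slice(img, mask, config, rng)
                bi.append(img)
                bm.append(mask)
            x = nn.Tensor(model.net_input(np.asarray(bi)))
            probs = model(x).log_softmax(axis=1).exp()
            if epoch < config.ce_warmup_epochs:
                loss = _pixel_cross_entropy(probs, np.asarray(bm))
            else:
                loss = dice_loss(probs, np.asarray(bm), include_background=True)
            if not np.isfinite(loss.data):
                raise RuntimeError("training aborted: non-finite loss")
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                norm = np.sqrt(sum(float((p.grad ** 2).sum())
                                   for p in model.parameters() if p.grad is not None))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if val is not None and len(val[0]):
            vl = []
            for lo in range(0, len(val[0]), config.batch_size):
                probs = model.predict_probabilities(val[0][lo:lo + config.batch_size])
                vl.append(dice_loss(probs, val[1][lo:lo + config.batch_size],
                                    include_background=True))
            vloss = float(np.mean(vl))
            history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val, best_state = vloss, model.state_dict()
        else:
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def train_segmenter(
    data: dict[str, tuple[VolumeStack, LabelVolume]],
    folds: list[FoldSplit],
    config: SegModelConfig,
) -> list[tuple[UNet, dict]]:
    """Train one model per cross-validation fold."""
    results = []
    for fold in folds:
        cfg = replace(config, seed=config.seed + fold.fold_index)
        results.append(train_one(data, fold.train_patients, fold.val_patients, cfg))
    return results


def segment_volume(model: UNet, stack: VolumeStack, batch_size: int = 8) -> LabelVolume:
    """Argmax labels for every sagittal slice of a stack (deterministic)."""
    vol = _normalize_stack(stack)
    out = np.empty(vol.shape, dtype=np.int16)
    for lo in range(0, vol.shape[0], batch_size):
        probs = model.predict_probabilities(vol[lo:lo + batch_size])
        out[lo:lo + probs.shape[0]] = probs.argmax(axis=1)
    return LabelVolume(out)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class SegMetrics:
    """Per-class confusion-derived segmentation metrics.

    Classes with an empty union in both masks are flagged (``empty``) and
    given metric 1.0; means are reported both with and without them.
    """

    classes: np.ndarray
    iou: np.ndarray
    f1: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    support: np.ndarray
    empty: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def mean(self, metric: str = "f1", include_empty: bool = False) -> float:
        vals = getattr(self, metric)
        keep = np.ones(len(vals), bool) if include_empty else ~self.empty
        return float(vals[keep].mean()) if keep.any() else float("nan")

    def micro(self, classes=None) -> dict[str, float]:
        """Pixel-pooled precision/recall/F1 over a class subset."""
        sel = np.isin(self.classes, classes) if classes is not None else ~self.empty
        tp = self._tp[sel].sum()
        fp = self._fp[sel].sum()
        fn = self._fn[sel].sum()
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return {"precision": float(prec), "recall": float(rec), "f1": float(f1)}


def segmentation_metrics(
    pred: LabelVolume, truth: LabelVolume, class_subset=None
) -> SegMetrics:
    """IoU / F1 / precision / recall per class from the voxel confusion matrix."""
    p = np.asarray(pred.labels).ravel()
    t = np.asarray(truth.labels).ravel()
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    classes = np.asarray(sorted(class_subset) if class_subset is not None
                         else sorted(set(CLASS_MAP) - {0}))
    tp = np.array([np.sum((p == c) & (t == c)) for c in classes], dtype=float)
    fp = np.array([np.sum((p == c) & (t != c)) for c in classes], dtype=float)
    fn = np.array([np.sum((p != c) & (t == c)) for c in classes], dtype=float)
    union = tp + fp + fn
    empty = union == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(empty, 1.0, tp / np.where(union, union, 1.0))
        precision = np.where(empty, 1.0, np.where(tp + fp, tp / np.where(tp + fp, tp + fp, 1.0), 0.0))
        recall = np.where(empty, 1.0, np.where(tp + fn, tp / np.where(tp + fn, tp + fn, 1.0), 0.0))
        f1 = np.where(empty, 1.0, 2 * tp / np.where(2 * tp + fp + fn, 2 * tp + fp + fn, 1.0))
    m = SegMetrics(
        classes=classes, iou=iou, f1=f1, precision=precision, recall=recall,
        support=np.array([np.sum(t == c) for c in classes]), empty=empty,
        class_names={int(c): CLASS_MAP.get(int(c), str(c)) for c in classes},
    )
    m._tp, m._fp, m._fn = tp, fp, fn
    return m
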