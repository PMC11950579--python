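"""Classifier training: augmentation, imbalance-aware composite loss, evaluation.

The objective is a weighted geometric mean of focal loss and
cross-entropy: with w = geo_weight and per-class weights offsetting the
grade imbalance,

    L = exp(w * log(L_focal + eps) + (1 - w) * log(L_CE + eps)),
    L_CE    = -weight_t * log(p_t),
    L_focal = -weight_t * (1 - p_t)^gamma * log(p_t),

with eps-flooring inside every log so a vanishing p_t never produces NaN.
Optimization uses AdamW (decoupled weight decay); augmentation applies a
random 3D rotation and Gaussian coordinate jitter, after which the graph
(features, encodings, edges) is rebuilt from the moved points.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .discgraph import DiscGraph, GraphConfig, build_disc_graph
from .gnn import ModelConfig, Prediction, build_model
from .phantom import LEVELS
from .reconstruction import DiscPointCloud

__all__ = [
    "TrainConfig",
    "ClassificationReport",
    "class_weights_from_counts",
    "focal_ce_geometric_loss",
    "augment_graph",
    "train_classifier",
    "aggregate_patient",
    "classification_report",
    "permutation_pvalue",
]

_EPS = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    focal_gamma: float = 2.0
    geo_weight: float = 0.5
    class_weights: tuple[float, ...] | None = None  # None = derive from train counts
    max_rotation_deg: float = 15.0
    jitter_sd: float = 0.01
    augment: bool = True
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.geo_weight <= 1.0:
            raise ValueError("geo_weight must be in [0, 1]")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be nonnegative")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, float)
            if w.shape != (5,) or (w <= 0).any():
                raise ValueError("class_weights must be 5 positive reals")


def class_weights_from_counts(counts) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    weight_g is proportional to 1/max(count_g, 1); scale-invariant in the
    counts, so doubling the cohort leaves the weights unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (5,) or (counts < 0).any():
        raise ValueError("counts must be 5 nonnegative integers")
    if counts.sum() == 0:
        raise ValueError("all class counts are zero")
    w = 1.0 / np.maximum(counts, 1.0)
    return w / w.mean()


def focal_ce_geometric_loss(probabilities, target_grade: int, config: TrainConfig):
    """Weighted geometric mean of focal and cross-entropy loss for one sample.

    Differentiable when given a Tensor of probabilities; returns a float
    for a plain array.  ``target_grade`` is the Pfirrmann grade 1..5.
    """
    if not 1 <= int(target_grade) <= 5:
        raise ValueError("target grade must be in 1..5")
    is_tensor = isinstance(probabilities, nn.Tensor)
    p = probabilities if is_tensor else nn.Tensor(np.asarray(probabilities, float))
    if p.shape != (5,):
        raise ValueError("probabilities must be a 5-vector")
    if np.abs(p.data.sum() - 1.0) > 1e-5 or (p.data < -1e-9).any():
        raise ValueError("probabilities must lie on the simplex")
    weights = (np.asarray(config.class_weights, float)
               if config.class_weights is not None else np.ones(5))
    w_t = float(weights[int(target_grade) - 1])
    t = int(target_grade) - 1
    p_t = p.gather(np.array([t])).reshape(())
    log_pt = (p_t + _EPS).log()
    l_ce = log_pt * (-w_t)
    l_focal = (1.0 - p_t) ** config.focal_gamma * log_pt * (-w_t)
    w = config.geo_weight
    loss = ((l_focal + _EPS).log() * w + (l_ce + _EPS).log() * (1.0 - w)).exp()
    return loss if is_tensor else float(loss.data)


def _random_rotation(max_deg: float, rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def augment_graph(
    graph: DiscGraph,
    config: TrainConfig,
    seed: int,
    graph_config: GraphConfig = GraphConfig(),
) -> DiscGraph:
    """Random rotation + Gaussian jitter, then full graph reconstruction.

    The label is untouched; features, positional encodings, and edges are
    recomputed from the moved, re-normalized coordinates.  With zero
    rotation and zero jitter the graph is returned unchanged.
    """
    if config.max_rotation_deg == 0 and config.jitter_sd == 0:
        return graph
    rng = np.random.default_rng(seed)
    rot = _random_rotation(config.max_rotation_deg, rng)
    pts = graph.coords @ rot.T
    if config.jitter_sd > 0:
        pts = pts + rng.normal(0.0, config.jitter_sd, pts.shape)
    intensity = graph.node_features[:, 0] if graph.has_intensity else None
    cloud = DiscPointCloud(
        pts, graph.meta.get("method", "voxel"), intensity,
        (graph.patient_id, graph.level),
    )
    return build_disc_graph(
        cloud, graph.label, graph_config, faces=graph.faces,
        level=graph.level, patient_id=graph.patient_id,
    )


def _check_patient_disjoint(train_graphs, val_graphs):
    tr = {g.patient_id for g in train_graphs if g.patient_id}
    va = {g.patient_id for g in val_graphs if g.patient_id}
    overlap = tr & va
    if overlap:
        raise ValueError(f"patients appear in both train and val: {sorted(overlap)[:5]}")


def train_classifier(
    train_graphs: list[DiscGraph],
    val_graphs: list[DiscGraph],
    model_config: ModelConfig,
    train_config: TrainConfig,
    graph_config: GraphConfig = GraphConfig(),
):
    """Epoch loop with augmentation, composite loss, and AdamW updates.

    Returns (model, history); the parameters of the best-validation epoch
    are retained.  A non-finite loss aborts the run and restores the last
    good checkpoint.
    """
    if not train_graphs:
        raise ValueError("training set is empty")
    _check_patient_disjoint(train_graphs, val_graphs)
    cfg = train_config
    if cfg.class_weights is None:
        counts = np.bincount([g.label - 1 for g in train_graphs], minlength=5)
        cfg = TrainConfig(**{**vars(cfg), "class_weights": tuple(class_weights_from_counts(counts))})
    model = build_model(model_config)
    opt = nn.AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": [], "aborted": False}
    best_state, best_val = model.state_dict(), np.inf
    try:
        for epoch in range(cfg.epochs):
            model.set_training(True)
            order = rng.permutation(len(train_graphs))
            losses = []
            for i in order:
                g = train_graphs[i]
                if cfg.augment:
                    g = augment_graph(g, cfg, seed=int(rng.integers(2 ** 31)),
                                      graph_config=graph_config)
                probs = model.logits(g).log_softmax().exp()
                loss = focal_ce_geometric_loss(probs, g.label, cfg)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history["train_loss"].append(float(np.mean(losses)))
            if val_graphs:
                model.set_training(False)
                vls, hits = [], 0
                for g in val_graphs:
                    pred = model(g)
                    vls.append(focal_ce_geometric_loss(pred.probabilities, g.label, cfg))
                    hits += pred.predicted_grade == g.label
                vloss = float(np.mean(vls))
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(hits / len(val_graphs))
                if vloss < best_val:
                    best_val, best_state = vloss, model.state_dict()
            else:
                best_state = model.state_dict()
    except FloatingPointError:
        history["aborted"] = True
    model.load_state_dict(best_state)
    model.set_training(False)
    return model, history


def aggregate_patient(predictions: list[Prediction]) -> Prediction:
    """Combine per-slice/per-sample predictions for one disc.

    Probability vectors are averaged and renormalized; argmax ties break
    toward the higher (more severe) grade, the clinically conservative
    choice.
    """
    if not predictions:
        raise ValueError("cannot aggregate an empty prediction list")
    provs = {p.provenance for p in predictions}
    if len(provs) > 1:
        raise ValueError(f"predictions span multiple discs: {sorted(provs)}")
    mean = np.mean([p.probabilities for p in predictions], axis=0)
    mean = mean / mean.sum()
    # argmax from the severe end so exact ties resolve upward
    grade = 5 - int(np.argmax(mean[::-1]))
    return Prediction(mean, grade, predictions[0].provenance)


@dataclass
class ClassificationReport:
    """One-vs-rest precision/recall/F1 per (level, grade) plus macro means.

    Cells with no true and no predicted member are undefined and stored
    as NaN rather than zero.
    """

    precision: pd.DataFrame  # index: level, columns: grade 1..5
    recall: pd.DataFrame
    f1: pd.DataFrame
    confusion: dict[str, np.ndarray] = field(default_factory=dict)
    n_discs: int = 0

    def level_macro(self, metric: str = "f1") -> pd.Series:
        return getattr(self, metric).mean(axis=1, skipna=True)

    def overall_macro(self, metric: str = "f1") -> float:
        return float(getattr(self, metric).stack().mean())

    def save(self, out_dir) -> None:
        """CSV per metric plus a heat-map figure, level x grade."""
        from pathlib import Path

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(1, 3, figsize=(13, 3.2))
        for ax, name in zip(axes, ("precision", "recall", "f1")):
            df = getattr(self, name)
            df.to_csv(out / f"{name}.csv")
            im = ax.imshow(df.to_numpy(), vmin=0, vmax=1, cmap="viridis")
            ax.set_xticks(range(df.shape[1]), [f"PF {g}" for g in df.columns])
            ax.set_yticks(range(df.shape[0]), df.index)
            ax.set_title(name)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(out / "report_heatmaps.png", dpi=120)
        plt.close(fig)


def classification_report(
    predictions: list[Prediction], truths: list[int], levels: list[str] | None = None
) -> ClassificationReport:
    """Per-level, per-grade one-vs-rest metrics from matched pairs."""
    if not predictions or len(predictions) != len(truths):
        raise ValueError("need matched, nonempty prediction/truth lists")
    if levels is None:
        levels = [p.provenance[1] or "all" for p in predictions]
    pred = np.array([p.predicted_grade for p in predictions])
    true = np.array(truths, dtype=int)
    lv = np.array(levels)
    level_order = [l for l in LEVELS if l in set(lv)] or sorted(set(lv))
    grades = list(range(1, 6))
    prec = pd.DataFrame(index=level_order, columns=grades, dtype=float)
    rec = pd.DataFrame(index=level_order, columns=grades, dtype=float)
    f1 = pd.DataFrame(index=level_order, columns=grades, dtype=float)
    confusion = {}
    for level in level_order:
        m = lv == level
        conf = np.zeros((5, 5), dtype=int)
        for t, p in zip(true[m], pred[m]):
            conf[t - 1, p - 1] += 1
        confusion[level] = conf
        for g in grades:
            tp = conf[g - 1, g - 1]
            fp = conf[:, g - 1].sum() - tp
            fn = conf[g - 1, :].sum() - tp
            if tp + fp + fn == 0:
                continue  # undefined cell stays NaN
            p_ = tp / (tp + fp) if tp + fp else 0.0
            r_ = tp / (tp + fn) if tp + fn else 0.0
            prec.loc[level, g] = p_
            rec.loc[level, g] = r_
            f1.loc[level, g] = 2 * p_ * r_ / (p_ + r_) if p_ + r_ > 0 else 0.0
    return ClassificationReport(prec, rec, f1, confusion, n_discs=len(true))


def permutation_pvalue(
    y_true, y_pred, metric, n_permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-sided permutation test: is metric(y_true, y_pred) above chance?

    The null distribution permutes the true labels against the fixed
    predictions; returns (observed, p_value) with the add-one estimator.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rng = np.random.default_rng(seed)
    observed = float(metric(y_true, y_pred))
    ge = 0
    for _ in range(n_permutations):
        if metric(rng.permutation(y_true), y_pred) >= observed:
            ge += 1
    return observed, (1 + ge) / (n_permutations + 1)
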