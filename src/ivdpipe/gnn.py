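"""Graph classifiers for Pfirrmann grading of disc point-cloud graphs.

Two architectures are provided:

* ``baseline_gcn`` — a stack of symmetric-normalized graph convolutions
  over the node features, global mean pooling, and a linear 5-class head.
* ``dual_graph`` — two subnetworks: a GCN branch over node features and a
  point-branch of hierarchical x-convolutions (learned transformations of
  k-nearest-neighbour patches with progressive farthest-point
  downsampling) over raw coordinates plus features; the two pooled
  embeddings are consolidated by multi-head self-attention over the
  2-token sequence before the softmax head.

Both are permutation-invariant at the graph level and operate on one
graph at a time (batching is an outer loop).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .discgraph import DiscGraph

__all__ = [
    "ModelConfig",
    "Prediction",
    "BaselineGCN",
    "DualGraphModel",
    "build_model",
    "gcn_normalized_adjacency",
    "farthest_point_indices",
]


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "dual_graph"  # or "baseline_gcn"
    in_features: int = 48
    hidden_dims: tuple[int, ...] = (64, 128, 256)
    n_classes: int = 5
    xconv_neighbors: int = 16
    attention_heads: int = 4
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("baseline_gcn", "dual_graph"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be nonempty")
        if self.n_classes != 5:
            raise ValueError("the Pfirrmann head is 5-class")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class Prediction:
    probabilities: np.ndarray  # 5-simplex, index 0 = grade 1
    predicted_grade: int
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (5,) or (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-5:
            raise ValueError("probabilities must be a 5-vector on the simplex")
        self.probabilities = p


def gcn_normalized_adjacency(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Dense D^-1/2 (A + I) D^-1/2 with symmetric, unweighted A.

    Self-loops make the operator fall back to the node's own features on
    edgeless graphs, so isolated nodes stay well defined.
    """
    a = np.zeros((n_nodes, n_nodes))
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if edges.size:
        a[edges[:, 0], edges[:, 1]] = 1.0
        a[edges[:, 1], edges[:, 0]] = 1.0
    a += np.eye(n_nodes)
    dinv = a.sum(axis=1) ** -0.5
    return a * dinv[:, None] * dinv[None, :]


def farthest_point_indices(points: np.ndarray, n_keep: int) -> np.ndarray:
    """Deterministic, permutation-invariant farthest-point subsampling.

    Starts from the point nearest the centroid (an intrinsic choice, so
    reordering the input permutes the result consistently) and greedily
    adds the point farthest from the current set.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n_keep >= n:
        return np.arange(n)
    start = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    chosen = [start]
    dist = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n_keep - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.asarray(chosen)


class _GCNLayer(nn.Module):
    def __init__(self, c_in, c_out, rng):
        self.lin = nn.Linear(c_in, c_out, rng)

    def forward(self, h: nn.Tensor, a_hat: nn.Tensor) -> nn.Tensor:
        return a_hat @ self.lin(h)


class _GCNBranch(nn.Module):
    def __init__(self, c_in, dims, dropout, rng):
        self.layers = []
        for c_out in dims:
            self.layers.append(_GCNLayer(c_in, c_out, rng))
            c_in = c_out
        self.dropout = nn.Dropout(dropout, rng)

    def forward(self, feats: nn.Tensor, a_hat: nn.Tensor) -> nn.Tensor:
        h = feats
        for layer in self.layers:
            h = self.dropout(layer(h, a_hat).relu())
        return h.mean(axis=0)  # permutation-invariant global pooling


class BaselineGCN(nn.Module):
    """Graph convolutions -> mean pooling -> linear 5-class head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.branch = _GCNBranch(config.in_features, config.hidden_dims, config.dropout, rng)
        self.head = nn.Linear(config.hidden_dims[-1], config.n_classes, rng)

    def logits(self, graph: DiscGraph) -> nn.Tensor:
        if graph.node_features.shape[1] != self.config.in_features:
            raise ValueError(
                f"graph has {graph.node_features.shape[1]} features, "
                f"model expects {self.config.in_features}"
            )
        a_hat = nn.Tensor(gcn_normalized_adjacency(graph.edges, graph.n_nodes))
        emb = self.branch(nn.Tensor(graph.node_features), a_hat)
        return self.head(emb.reshape(1, -1)).reshape(-1)

    def forward(self, graph: DiscGraph) -> Prediction:
        probs = self.logits(graph).log_softmax().exp().data
        return Prediction(probs, int(np.argmax(probs)) + 1, (graph.patient_id, graph.level))

    def set_training(self, flag: bool) -> None:
        _set_training(self, flag)


class _XConv(nn.Module):
    """PointCNN-style x-convolution over k-nearest-neighbour patches.

    For each representative point, local neighbour offsets are lifted to
    features by a pointwise MLP, a learned K x K transform (from the
    flattened patch geometry) reorders/weights the patch, and a dense map
    over the flattened patch produces the output feature.
    """

    def __init__(self, c_in, c_out, k, rng, c_lift=None):
        self.k = k
        c_lift = c_lift or max(c_out // 4, 8)
        self.lift1 = nn.Linear(3, c_lift, rng)
        self.lift2 = nn.Linear(c_lift, c_lift, rng)
        self.trans1 = nn.Linear(3 * k, k * k, rng)
        self.trans2 = nn.Linear(k * k, k * k, rng)
        self.out = nn.Linear(k * (c_lift + c_in), c_out, rng)
        self.c_lift = c_lift

    def forward(self, points: np.ndarray, feats: nn.Tensor, rep_idx: np.ndarray):
        k = self.k
        _, nbr = cKDTree(points).query(points[rep_idx], k=k)
        nbr = np.atleast_2d(nbr)
        local = points[nbr] - points[rep_idx][:, None, :]  # (R, K, 3) constant
        local_t = nn.Tensor(local)
        lifted = self.lift2(self.lift1(local_t).relu()).relu()  # (R, K, c_lift)
        gathered = feats.gather(nbr)  # (R, K, c_in)
        patch = nn.concat([lifted, gathered], axis=-1)  # (R, K, c_lift + c_in)
        r = len(rep_idx)
        xt = self.trans2(self.trans1(local_t.reshape(r, 3 * k)).relu()).reshape(r, k, k)
        mixed = xt @ patch  # (R, K, C)
        return self.out(mixed.reshape(r, -1)).relu(), points[rep_idx]


class _PointBranch(nn.Module):
    """Two x-convolution stages with farthest-point downsampling, then pooling."""

    def __init__(self, c_in, dims, k, dropout, rng):
        d1 = dims[0]
        d2 = dims[min(1, len(dims) - 1)]
        self.k = k
        self.conv1 = _XConv(c_in, d1, k, rng)
        self.conv2 = _XConv(d1, d2, k, rng)
        self.proj = nn.Linear(d2, dims[-1], rng)
        self.dropout = nn.Dropout(dropout, rng)

    def forward(self, points: np.ndarray, feats: nn.Tensor) -> nn.Tensor:
        n = len(points)
        r1 = farthest_point_indices(points, max(n // 4, self.k))
        h, pts = self.conv1(points, feats, r1)
        h = self.dropout(h)
        r2 = farthest_point_indices(pts, max(len(pts) // 4, min(self.k, len(pts))))
        h, _ = self.conv2(pts, h, r2)
        return self.proj(h.mean(axis=0).reshape(1, -1)).reshape(-1)


class _TwoTokenAttention(nn.Module):
    """Multi-head self-attention over the (gcn, point) embedding pair."""

    def __init__(self, dim, heads, rng):
        if dim % heads:
            raise ValueError("embedding dim must be divisible by attention_heads")
        self.heads = heads
        self.dh = dim // heads
        self.wq = nn.Linear(dim, dim, rng)
        self.wk = nn.Linear(dim, dim, rng)
        self.wv = nn.Linear(dim, dim, rng)
        self.wo = nn.Linear(dim, dim, rng)

    def forward(self, tokens: nn.Tensor) -> nn.Tensor:  # tokens: (2, dim)
        h, dh = self.heads, self.dh
        q = self.wq(tokens).reshape(2, h, dh).transpose(1, 0, 2)  # (h, 2, dh)
        k = self.wk(tokens).reshape(2, h, dh).transpose(1, 0, 2)
        v = self.wv(tokens).reshape(2, h, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (dh ** -0.5)  # (h, 2, 2)
        attn = scores.log_softmax(axis=-1).exp()
        mixed = (attn @ v).transpose(1, 0, 2).reshape(2, h * dh)
        return self.wo(mixed).mean(axis=0)  # pool the 2 tokens


class DualGraphModel(nn.Module):
    """GCN branch + x-convolution branch consolidated by attention."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dims[-1]
        self.gcn = _GCNBranch(config.in_features, config.hidden_dims, config.dropout, rng)
        self.points = _PointBranch(
            config.in_features, config.hidden_dims, config.xconv_neighbors, config.dropout, rng
        )
        self.attention = _TwoTokenAttention(d, config.attention_heads, rng)
        self.head = nn.Linear(d, config.n_classes, rng)

    def _embeddings(self, graph: DiscGraph) -> tuple[nn.Tensor, nn.Tensor]:
        if graph.n_nodes < self.config.xconv_neighbors:
            raise ValueError(
                f"cloud has {graph.n_nodes} points; the x-convolution branch needs at "
                f"least xconv_neighbors={self.config.xconv_neighbors} points"
            )
        if graph.node_features.shape[1] != self.config.in_features:
            raise ValueError("feature width mismatch")
        a_hat = nn.Tensor(gcn_normalized_adjacency(graph.edges, graph.n_nodes))
        feats = nn.Tensor(graph.node_features)
        e_gcn = self.gcn(feats, a_hat)
        e_pts = self.points(graph.coords, feats)
        return e_gcn, e_pts

    def logits(self, graph: DiscGraph, zero_point_branch: bool = False) -> nn.Tensor:
        e_gcn, e_pts = self._embeddings(graph)
        if zero_point_branch:  # ablation hook: silence branch B
            e_pts = e_pts * 0.0
        consolidated = self.attention(nn.stack([e_gcn, e_pts], axis=0))
        return self.head(consolidated.reshape(1, -1)).reshape(-1)

    def forward(self, graph: DiscGraph, zero_point_branch: bool = False) -> Prediction:
        probs = self.logits(graph, zero_point_branch).log_softmax().exp().data
        return Prediction(probs, int(np.argmax(probs)) + 1, (graph.patient_id, graph.level))

    def set_training(self, flag: bool) -> None:
        _set_training(self, flag)


def _set_training(module: nn.Module, flag: bool) -> None:
    stack = [module]
    while stack:
        obj = stack.pop()
        if isinstance(obj, nn.Dropout):
            obj.training = flag
        elif isinstance(obj, nn.Module):
            stack.extend(vars(obj).values())
        elif isinstance(obj, (list, tuple)):
            stack.extend(obj)


def build_model(config: ModelConfig):
    if config.architecture == "baseline_gcn":
        return BaselineGCN(config)
    return DualGraphModel(config)
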