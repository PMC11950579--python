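"""Disc point clouds as feature-rich graphs for the classifier.

Node features follow a fixed, versioned column layout (F = 48):

    0       voxel intensity (zero-filled with a flag when unavailable)
    1       Euclidean distance to the cloud centroid ("nucleus distance")
    2–7     distances to the six hypernodes (extreme point per axis/direction)
    8–27    Laplacian-eigenvector positional encoding (k = 20)
    28–47   random-walk return-probability positional encoding (t = 1..20)

Coordinates are normalized to [-1, 1] isotropically about the centroid, so
the 0.1 radius used for edge construction is scale-free.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .reconstruction import DiscPointCloud

__all__ = [
    "FEATURE_LAYOUT_VERSION",
    "GraphConfig",
    "DiscGraph",
    "normalize_coords",
    "center_distance",
    "hypernode_distances",
    "radius_edges",
    "faces_to_edges",
    "laplacian_pe",
    "random_walk_pe",
    "build_disc_graph",
    "save_graph",
    "load_graph",
]

FEATURE_LAYOUT_VERSION = 1


@dataclass(frozen=True)
class GraphConfig:
    radius: float = 0.1
    lap_pe_dim: int = 20
    rw_pe_steps: int = 20
    max_degree: int | None = None  # None = unbounded
    use_faces: bool = False  # concatenate face-derived edges with radius edges


@dataclass
class DiscGraph:
    """Normalized point cloud with features, edges, and a Pfirrmann label."""

    coords: np.ndarray  # P x 3 in [-1, 1]
    node_features: np.ndarray  # P x 48
    edges: np.ndarray  # E x 2 directed pairs, symmetric closure, no self loops
    label: int  # Pfirrmann grade 1..5
    level: str = ""
    patient_id: str = ""
    faces: np.ndarray | None = None
    has_intensity: bool = True
    layout_version: int = FEATURE_LAYOUT_VERSION
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.abs(self.coords).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("coordinates must lie in [-1, 1]")
        if not np.isfinite(self.node_features).all():
            raise ValueError("node features must be finite")
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


# ---------------------------------------------------------------------------
# geometry

def normalize_coords(points: np.ndarray) -> tuple[np.ndarray, dict]:
    """Isotropic rescale about the centroid so max |coordinate| = 1.

    Aspect ratios are preserved (one scale for all axes).  Returns the
    normalized coordinates and the affine transform {center, scale} with
    x_norm = (x - center) / scale.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least two 3D points")
    center = pts.mean(axis=0)
    centered = pts - center
    scale = np.abs(centered).max()
    if scale <= 0:
        raise ValueError("degenerate extent: all points identical")
    return centered / scale, {"center": center, "scale": float(scale)}


def center_distance(coords: np.ndarray) -> np.ndarray:
    """Per-node Euclidean distance to the centroid (nucleus analogue)."""
    coords = np.asarray(coords, dtype=float)
    return np.linalg.norm(coords - coords.mean(axis=0), axis=1)


def hypernode_distances(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances to the six extreme nodes (argmin/argmax per axis).

    Hypernodes are actual cloud members: for each of the three axes the
    node attaining the minimum and the maximum coordinate (ties broken
    toward the lowest index, numpy argmin/argmax convention).  Returns the
    P x 6 distance matrix and the 6 hypernode indices, column order
    (min_x, max_x, min_y, max_y, min_z, max_z).
    """
    coords = np.asarray(coords, dtype=float)
    idx = []
    for axis in range(3):
        idx.append(int(np.argmin(coords[:, axis])))
        idx.append(int(np.argmax(coords[:, axis])))
    hyper = coords[idx]  # 6 x 3
    dists = np.linalg.norm(coords[:, None, :] - hyper[None, :, :], axis=2)
    return dists, np.asarray(idx)


# ---------------------------------------------------------------------------
# edges

def _symmetrize(pairs: np.ndarray) -> np.ndarray:
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    both = np.vstack([pairs, pairs[:, ::-1]])
    return np.unique(both, axis=0)


def radius_edges(
    coords: np.ndarray, radius: float = 0.1, max_degree: int | None = None
) -> np.ndarray:
    """All directed pairs (i, j) with 0 < ||ci - cj|| <= radius.

    With ``max_degree`` set, each node keeps only its nearest
    ``max_degree`` in-radius neighbours before the symmetric closure.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if max_degree is not None and pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = np.zeros(len(pairs), dtype=bool)
        directed = np.vstack([pairs, pairs[:, ::-1]])
        dd = np.concatenate([d, d])
        order = np.lexsort((dd, directed[:, 0]))
        counts: dict[int, int] = {}
        keep_dir = np.zeros(len(directed), dtype=bool)
        for oi in order:
            i = directed[oi, 0]
            c = counts.get(i, 0)
            if c < max_degree:
                keep_dir[oi] = True
                counts[i] = c + 1
        kept = directed[keep_dir]
        return _symmetrize(kept)
    return _symmetrize(pairs)


def faces_to_edges(faces: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Undirected edge set of a triangle list (deduplicated, symmetric)."""
    faces = np.asarray(faces, dtype=int).reshape(-1, 3)
    if n_nodes is not None and faces.size and faces.max() >= n_nodes:
        raise ValueError("face index out of range")
    if faces.size and faces.min() < 0:
        raise ValueError("face index out of range")
    pairs = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    return _symmetrize(pairs)


def undirected_edge_count(edges: np.ndarray) -> int:
    if edges.size == 0:
        return 0
    return len(np.unique(np.sort(edges, axis=1), axis=0))


# ---------------------------------------------------------------------------
# positional encodings

def _adjacency(edges: np.ndarray, n_nodes: int) -> sp.csr_matrix:
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    data = np.ones(len(edges))
    a = sp.csr_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n_nodes, n_nodes))
    a = ((a + a.T) > 0).astype(float)  # symmetric, unweighted
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def laplacian_pe(edges: np.ndarray, n_nodes: int, k: int = 20) -> np.ndarray:
    """Eigenvectors of the symmetric normalized Laplacian as node encodings.

    Per connected component, the k eigenvectors with smallest nonzero
    eigenvalue are taken, unit-normalized, sign-fixed so the
    largest-magnitude entry is positive, and written into that
    component's rows; remaining columns are zero-padded.  An edgeless
    graph therefore has an all-zero encoding.
    """
    if n_nodes == 0:
        raise ValueError("graph has no nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    pe = np.zeros((n_nodes, k))
    a = _adjacency(edges, n_nodes)
    if a.nnz == 0:
        return pe
    n_comp, comp = connected_components(a, directed=False)
    for c in range(n_comp):
        nodes = np.flatnonzero(comp == c)
        if len(nodes) < 2:
            continue
        sub = a[np.ix_(nodes, nodes)].toarray()
        deg = sub.sum(axis=1)
        dinv = np.where(deg > 0, deg ** -0.5, 0.0)
        lap = np.eye(len(nodes)) - (dinv[:, None] * sub) * dinv[None, :]
        w, v = np.linalg.eigh((lap + lap.T) / 2.0)
        nz = w > 1e-8
        w, v = w[nz], v[:, nz]
        order = np.argsort(w)[:k]
        vecs = v[:, order]
        for j in range(vecs.shape[1]):
            col = vecs[:, j]
            col = col / np.linalg.norm(col)
            if col[np.argmax(np.abs(col))] < 0:
                col = -col
            pe[nodes, j] = col
    return pe


def random_walk_pe(edges: np.ndarray, n_nodes: int, steps: int = 20) -> np.ndarray:
    """Return probabilities diag((D^-1 A)^t) for t = 1..steps.

    Isolated nodes are given a self-loop so their walk is well defined
    (they return with probability 1 at every step).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    a = _adjacency(edges, n_nodes).toarray()
    iso = a.sum(axis=1) == 0
    a[iso, iso] = 1.0
    p = a / a.sum(axis=1, keepdims=True)
    pe = np.empty((n_nodes, steps))
    m = p.copy()
    pe[:, 0] = np.diag(m)
    for t in range(1, steps):
        m = m @ p
        pe[:, t] = np.diag(m)
    return pe


# ---------------------------------------------------------------------------
# assembly

def build_disc_graph(
    cloud: DiscPointCloud,
    grade: int,
    config: GraphConfig = GraphConfig(),
    faces: np.ndarray | None = None,
    level: str = "",
    patient_id: str = "",
) -> DiscGraph:
    """Assemble the full 48-feature graph from a sampled disc point cloud."""
    coords, transform = normalize_coords(cloud.points)
    edges = radius_edges(coords, config.radius, config.max_degree)
    if config.use_faces and faces is not None:
        edges = _symmetrize(np.vstack([edges, faces_to_edges(faces, len(coords))]))
    has_intensity = cloud.intensity is not None
    intensity = cloud.intensity if has_intensity else np.zeros(len(coords))
    hyper, hyper_idx = hypernode_distances(coords)
    features = np.column_stack(
        [
            intensity,
            center_distance(coords),
            hyper,
            laplacian_pe(edges, len(coords), config.lap_pe_dim),
            random_walk_pe(edges, len(coords), config.rw_pe_steps),
        ]
    )
    if not patient_id or not level:
        patient_id = patient_id or cloud.provenance[0]
        level = level or cloud.provenance[1]
    return DiscGraph(
        coords=coords,
        node_features=features,
        edges=edges,
        label=int(grade),
        level=level,
        patient_id=patient_id,
        faces=faces,
        has_intensity=has_intensity,
        meta={"transform": {k: np.asarray(v).tolist() for k, v in transform.items()},
              "hypernodes": hyper_idx.tolist(), "method": cloud.method},
    )


# ---------------------------------------------------------------------------
# serialization: one .npz per disc plus CSV interchange

def save_graph(graph: DiscGraph, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        coords=graph.coords,
        node_features=graph.node_features,
        edges=graph.edges,
        label=np.int64(graph.label),
        faces=graph.faces if graph.faces is not None else np.empty((0, 3), int),
        header=np.bytes_(json.dumps({
            "layout_version": graph.layout_version,
            "level": graph.level,
            "patient_id": graph.patient_id,
            "has_intensity": graph.has_intensity,
            "meta": graph.meta,
        })),
    )


def load_graph(path: str | Path) -> DiscGraph:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(bytes(z["header"]).decode())
        faces = z["faces"]
        return DiscGraph(
            coords=z["coords"],
            node_features=z["node_features"],
            edges=z["edges"],
            label=int(z["label"]),
            level=header["level"],
            patient_id=header["patient_id"],
            faces=faces if faces.size else None,
            has_intensity=header["has_intensity"],
            layout_version=header["layout_version"],
            meta=header["meta"],
        )


def export_graph_csv(graph: DiscGraph, prefix: str | Path) -> tuple[Path, Path]:
    """Generic interchange: node-attribute CSV + edge-list CSV."""
    import pandas as pd

    prefix = Path(prefix)
    nodes = pd.DataFrame(
        np.column_stack([graph.coords, graph.node_features]),
        columns=[*"xyz"] + [f"f{i}" for i in range(graph.node_features.shape[1])],
    )
    node_path = prefix.with_suffix(".nodes.csv")
    edge_path = prefix.with_suffix(".edges.csv")
    nodes.to_csv(node_path, index=False)
    pd.DataFrame(graph.edges, columns=["src", "dst"]).to_csv(edge_path, index=False)
    return node_path, edge_path
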