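"""Attributed region-adjacency graphs built from a parcellation.

Each trial's activation map becomes one graph: nodes are parcels, an edge links
two parcels whose points touch in the point-neighborhood graph, and every node
carries two real-valued attributes — the parcel's centre of mass in the ROI
coordinate system (geometric) and the trial's mean activation inside the parcel
(activation).  Within a subject, structure and geometry are shared across
trials; only the activation attributes and the label change.  Attributes stay
real-valued throughout: no quantization into discrete labels anywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import sparse

from .parcellation import Parcellation
from .synthetic import ROIData


@dataclass
class PatternGraph:
    """Attributed relational graph of one trial's activation pattern."""

    adjacency: np.ndarray   # (q, q) binary symmetric, zero diagonal
    geom: np.ndarray        # (q, 2) parcel centres of mass
    activation: np.ndarray  # (q,) parcel mean activations
    label: int | str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.geom = np.asarray(self.geom, dtype=float)
        self.activation = np.asarray(self.activation, dtype=float)
        q = self.adjacency.shape[0]
        if self.adjacency.shape != (q, q):
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        if self.geom.shape != (q, 2) or self.activation.shape != (q,):
            raise ValueError("attribute shapes must match the node count")
        if not (np.isfinite(self.geom).all() and np.isfinite(self.activation).all()):
            raise ValueError("attributes must be finite")

    @property
    def q(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Undirected edge count."""
        return int(self.adjacency.sum()) // 2

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Ordered (i, j) node-index arrays over both orientations of each edge."""
        return np.nonzero(self.adjacency)

    def permuted(self, perm: np.ndarray) -> "PatternGraph":
        """Graph with node ids relabeled by ``perm`` (new_index = position in perm)."""
        perm = np.asarray(perm)
        return PatternGraph(self.adjacency[np.ix_(perm, perm)], self.geom[perm],
                            self.activation[perm], self.label, self.subject_id)


def parcel_adjacency(parcellation: Parcellation, point_adj: sparse.spmatrix) -> np.ndarray:
    """Region-adjacency matrix: parcels touch iff some of their points neighbor."""
    coo = sparse.coo_matrix(point_adj)
    pi = parcellation.assignment[coo.row]
    pj = parcellation.assignment[coo.col]
    q = parcellation.q
    adj = np.zeros((q, q), dtype=int)
    mask = pi != pj
    adj[pi[mask], pj[mask]] = 1
    adj = np.maximum(adj, adj.T)
    return adj


def activation_attributes(parcellation: Parcellation, activation_column: np.ndarray) -> np.ndarray:
    """Per-parcel mean of one trial's activation map."""
    activation_column = np.asarray(activation_column, dtype=float)
    if activation_column.shape[0] != len(parcellation.assignment):
        raise ValueError("activation column length must match the ROI point count")
    sums = np.bincount(parcellation.assignment, weights=activation_column,
                       minlength=parcellation.q)
    return sums / parcellation.parcel_sizes


def geometric_attributes(parcellation: Parcellation, coords: np.ndarray) -> np.ndarray:
    """Per-parcel unweighted centre of mass in the ROI's coordinate system."""
    coords = np.asarray(coords, dtype=float)
    sizes = parcellation.parcel_sizes
    out = np.empty((parcellation.q, coords.shape[1]))
    for d in range(coords.shape[1]):
        out[:, d] = np.bincount(parcellation.assignment, weights=coords[:, d],
                                minlength=parcellation.q) / sizes
    return out


def build_graphs(roi: ROIData, parcellation: Parcellation,
                 point_adj: sparse.spmatrix | None = None) -> list[PatternGraph]:
    """One attributed graph per trial; structure and geometry shared across trials."""
    if point_adj is None:
        from .parcellation import point_adjacency
        point_adj = point_adjacency(roi.coords)
    adjacency = parcel_adjacency(parcellation, point_adj)
    geom = geometric_attributes(parcellation, roi.coords)
    return [PatternGraph(adjacency, geom,
                         activation_attributes(parcellation, roi.activations[:, t]),
                         label=roi.labels[t], subject_id=roi.subject_id)
            for t in range(roi.n_trials)]


def normalize_activation(roi: ROIData) -> ROIData:
    """Linearly rescale each trial map to [0, 1] within the ROI.

    A constant trial map has no range and maps to all zeros (with a warning).
    """
    acts = roi.activations
    lo = acts.min(axis=0)
    span = acts.max(axis=0) - lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant trial map(s) normalized to zeros",
                      stacklevel=2)
    span = np.where(degenerate, 1.0, span)
    scaled = (acts - lo) / span
    scaled[:, degenerate] = 0.0
    return ROIData(roi.subject_id, roi.coords.copy(), scaled, roi.labels.copy())


# ---------------------------------------------------------------------------
# serialization — GraphML (one graph per file) and a JSON dialect (graph lists);
# both round-trip to full float precision


def to_networkx(graph: PatternGraph) -> nx.Graph:
    g = nx.Graph()
    if graph.label is not None:
        g.graph["label"] = int(graph.label)
    if graph.subject_id is not None:
        g.graph["subject_id"] = graph.subject_id
    for i in range(graph.q):
        g.add_node(i, x=float(graph.geom[i, 0]), y=float(graph.geom[i, 1]),
                   activation=float(graph.activation[i]))
    ii, jj = np.nonzero(np.triu(graph.adjacency))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def from_networkx(g: nx.Graph) -> PatternGraph:
    nodes = sorted(g.nodes)
    index = {n: k for k, n in enumerate(nodes)}
    q = len(nodes)
    adjacency = np.zeros((q, q), dtype=int)
    for u, v in g.edges:
        adjacency[index[u], index[v]] = adjacency[index[v], index[u]] = 1
    geom = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in nodes])
    activation = np.array([g.nodes[n]["activation"] for n in nodes])
    return PatternGraph(adjacency, geom, activation,
                        label=g.graph.get("label"), subject_id=g.graph.get("subject_id"))


def write_graphml(graph: PatternGraph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(graph), str(path))


def read_graphml(path: str | Path) -> PatternGraph:
    g = nx.read_graphml(str(path), node_type=int)
    return from_networkx(g)


def graphs_to_json(graphs: list[PatternGraph], path: str | Path) -> None:
    records = [{"adjacency": g.adjacency.tolist(),
                "geom": [[v.hex() for v in row] for row in g.geom.astype(float)],
                "activation": [v.hex() for v in g.activation.astype(float)],
                "label": None if g.label is None else int(g.label),
                "subject_id": g.subject_id}
               for g in graphs]
    Path(path).write_text(json.dumps(records))


def graphs_from_json(path: str | Path) -> list[PatternGraph]:
    records = json.loads(Path(path).read_text())
    return [PatternGraph(np.array(r["adjacency"]),
                         np.array([[float.fromhex(v) for v in row] for row in r["geom"]]),
                         np.array([float.fromhex(v) for v in r["activation"]]),
                         label=r["label"], subject_id=r["subject_id"])
            for r in records]
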