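"""Spatially constrained Ward parcellation of a region of interest.

A parcellation partitions the ROI's points into ``q`` spatially connected
parcels by agglomerative Ward clustering in which only spatially adjacent
parcels may merge.  The clustering features combine standardized point
coordinates (spatial regularization) with the standardized per-trial
activation values (full functional information), so the parcels are
anatomo-functional units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import kneighbors_graph

from .synthetic import ROIData


@dataclass
class Parcellation:
    """Point-to-parcel assignment with parcel ids ``0 .. q-1``."""

    assignment: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        present = np.unique(self.assignment)
        if not np.array_equal(present, np.arange(self.q)):
            raise ValueError("assignment must use every parcel id 0..q-1 exactly")

    @property
    def parcel_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.q)

    def points_of(self, parcel: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == parcel)


def point_adjacency(coords: np.ndarray, mode: str = "grid4", k: int = 6) -> sparse.csr_matrix:
    """Binary symmetric point-neighborhood graph over ROI points.

    ``grid4`` connects points at unit L1 distance (4-connectivity on a pixel
    grid); ``knn`` uses the symmetrized union of k-nearest-neighbor relations.
    Emits a warning if the resulting graph is disconnected.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if mode == "grid4":
        pairs = cKDTree(coords).query_pairs(r=1.0 + 1e-9, output_type="ndarray")
        # unit L2 radius on an integer grid == unit L1 distance
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    elif mode == "knn":
        g = kneighbors_graph(coords, n_neighbors=min(k, n - 1), mode="connectivity")
        adj = ((g + g.T) > 0).astype(float).tocsr()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_comp = sparse.csgraph.connected_components(adj, directed=False, return_labels=False)
    if n_comp > 1:
        warnings.warn(f"point graph has {n_comp} connected components; "
                      "parcels may not all be spatially connected", stacklevel=2)
    return adj


def _standardize_block(block: np.ndarray) -> np.ndarray:
    """Z-score columns; constant columns map to 0."""
    mean = block.mean(axis=0)
    std = block.std(axis=0)
    std[std == 0] = 1.0
    return (block - mean) / std


def _features(coords: np.ndarray, activations: np.ndarray,
              feature_weights: tuple[float, float]) -> np.ndarray:
    """Stack standardized geometric and functional blocks.

    Each block is additionally scaled by 1/sqrt(its column count) so the two
    sources contribute comparably regardless of trial count, and duplicated
    activation columns (e.g. identical subjects in group mode) do not change
    the Ward merge order.
    """
    w_geo, w_fun = feature_weights
    geo = _standardize_block(np.asarray(coords, dtype=float))
    fun = _standardize_block(np.asarray(activations, dtype=float))
    geo = geo * (w_geo / np.sqrt(geo.shape[1]))
    fun = fun * (w_fun / np.sqrt(fun.shape[1]))
    return np.hstack([geo, fun])


def _ward_cut(features: np.ndarray, connectivity: sparse.csr_matrix, q: int) -> np.ndarray:
    n = features.shape[0]
    if not 1 <= q <= n:
        raise ValueError(f"q must be in [1, {n}], got {q}")
    if q == n:
        return np.arange(n)
    if q == 1:
        return np.zeros(n, dtype=int)
    model = AgglomerativeClustering(n_clusters=q, linkage="ward", connectivity=connectivity)
    with warnings.catch_warnings():
        # sklearn warns when it stitches a disconnected graph; we warned already
        warnings.simplefilter("ignore")
        raw = model.fit_predict(features)
    return _canonical_labels(raw)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel parcels by order of first appearance for platform-stable ids."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def ward_parcellate(roi: ROIData, q: int,
                    feature_weights: tuple[float, float] = (1.0, 1.0),
                    point_adj: sparse.csr_matrix | None = None) -> Parcellation:
    """Learn a q-parcel spatially constrained Ward parcellation for one subject."""
    if roi.n_trials < 1:
        raise ValueError("roi must have at least one trial")
    if point_adj is None:
        point_adj = point_adjacency(roi.coords)
    features = _features(roi.coords, roi.activations, feature_weights)
    return Parcellation(_ward_cut(features, point_adj, q), q)


def group_parcellate(rois: list[ROIData], q: int,
                     feature_weights: tuple[float, float] = (1.0, 1.0),
                     point_adj: sparse.csr_matrix | None = None) -> Parcellation:
    """Learn one shared parcellation from several subjects in a common space.

    Functional features from all subjects are concatenated trial-wise; all
    subjects must share the same point coordinates.
    """
    if not rois:
        raise ValueError("need at least one subject")
    coords = rois[0].coords
    for roi in rois[1:]:
        if not np.array_equal(roi.coords, coords):
            raise ValueError("group parcellation requires identical coords across subjects")
    if point_adj is None:
        point_adj = point_adjacency(coords)
    activations = np.hstack([roi.activations for roi in rois])
    features = _features(coords, activations, feature_weights)
    return Parcellation(_ward_cut(features, point_adj, q), q)


def parcel_is_connected(parcellation: Parcellation, point_adj: sparse.csr_matrix,
                        parcel: int) -> bool:
    """True if the parcel's points form a connected subgraph of the point graph."""
    idx = parcellation.points_of(parcel)
    if len(idx) <= 1:
        return True
    sub = point_adj[np.ix_(idx, idx)]
    n_comp = sparse.csgraph.connected_components(sub, directed=False, return_labels=False)
    return n_comp == 1
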