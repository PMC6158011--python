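"""Skeleton forests: the geometric data model shared by all analyses.

A skeleton is a tree of 3D nodes (positions in physical nanometres) with
unordered edges, optional radii and per-node annotation tags (``varicosity``,
``branchpoint``, ``seed``, free-text comments).  All downstream measurements
— path length, marching-sphere neighborhoods, bounding-box traversal — are
defined on this container.

Conventions
-----------
* All geometry lives in physical nanometres.  Voxel-to-nm conversion happens
  exactly once, at I/O time (see :mod:`axonmatch.io_formats`).
* Spatial membership predicates are *closed*: a node exactly on a box face or
  exactly at distance ``r`` from a query point counts as inside.
* Skeletons are strict trees.  Inputs with cycles or dangling edges are
  rejected (``SkeletonStructureError``); only duplicate edges may be repaired
  explicitly via :func:`dedupe_edges`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree


class SkeletonStructureError(ValueError):
    """Raised when an edge list does not describe a valid tree."""


@dataclass
class DatasetGeometry:
    """Voxel grid metadata for one imaging modality (LM or EM)."""

    voxel_size: np.ndarray  # nm / voxel, shape (3,)
    dataset_extent: np.ndarray | None = None  # voxels, shape (3,)
    frame_label: str = "EM"

    def __post_init__(self):
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be a positive 3-vector")
        if self.dataset_extent is not None:
            self.dataset_extent = np.asarray(self.dataset_extent)


@dataclass
class BBox:
    """Axis-aligned box given by center and half extent, both in nm."""

    center: np.ndarray
    half_extent: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.half_extent = np.asarray(self.half_extent, dtype=float)
        if self.center.shape != (3,) or self.half_extent.shape != (3,):
            raise ValueError("center and half_extent must be 3-vectors")
        if np.any(self.half_extent <= 0):
            raise ValueError("half_extent components must be > 0")

    @classmethod
    def cube(cls, center, edge_nm: float) -> "BBox":
        """Cubic box of the given edge length."""
        return cls(np.asarray(center, dtype=float), np.full(3, edge_nm / 2.0))

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Closed-box membership for an (n, 3) position array."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        return np.all(np.abs(pos - self.center) <= self.half_extent, axis=1)


class Skeleton:
    """A single tree of annotated 3D nodes.

    Parameters
    ----------
    tree_id : int
    node_ids : (n,) int array of unique node ids
    positions : (n, 3) float array, nm
    edges : (m, 2) int array of node-id pairs (unordered)
    radii : optional (n,) float array, nm
    annotations : mapping node_id -> set of tag strings
    name : display name
    validate : verify the edge graph is a tree (default True)
    """

    def __init__(self, tree_id, node_ids, positions, edges, radii=None,
                 annotations=None, name="", validate=True):
        self.tree_id = int(tree_id)
        self.name = name
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.edges = (np.asarray(edges, dtype=np.int64).reshape(-1, 2)
                      if len(edges) else np.empty((0, 2), dtype=np.int64))
        self.radii = None if radii is None else np.asarray(radii, dtype=float)
        self.annotations = {int(k): set(v) for k, v in (annotations or {}).items()}
        self._id_to_index = {int(i): k for k, i in enumerate(self.node_ids)}
        if validate:
            self._validate()

    # -- structure -------------------------------------------------------

    def _validate(self):
        n = len(self.node_ids)
        if not np.all(np.isfinite(self.positions)):
            raise SkeletonStructureError("non-finite node position")
        if len(self._id_to_index) != n:
            raise SkeletonStructureError("duplicate node ids within tree")
        if self.radii is not None and np.any(self.radii < 0):
            raise SkeletonStructureError("negative radius")
        m = len(self.edges)
        if m:
            known = set(self._id_to_index)
            ends = set(self.edges.ravel().tolist())
            if not ends <= known:
                raise SkeletonStructureError("edge references unknown node id")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise SkeletonStructureError("self-edge")
            keys = {frozenset(e) for e in self.edges.tolist()}
            if len(keys) != m:
                raise SkeletonStructureError("duplicate edge")
        if m != n - 1:
            raise SkeletonStructureError(
                f"{n} nodes with {m} edges is not a tree")
        if n > 1:
            g = nx.Graph()
            g.add_nodes_from(self.node_ids.tolist())
            g.add_edges_from(self.edges.tolist())
            if not nx.is_connected(g):
                raise SkeletonStructureError("edge graph not connected")
            # n-1 edges + connected => acyclic

    def __len__(self):
        return len(self.node_ids)

    def index_of(self, node_id: int) -> int:
        return self._id_to_index[int(node_id)]

    @property
    def edge_indices(self) -> np.ndarray:
        """Edges as (m, 2) row indices into ``positions``."""
        if not len(self.edges):
            return np.empty((0, 2), dtype=np.int64)
        lut = self._id_to_index
        return np.array([[lut[a], lut[b]] for a, b in self.edges.tolist()],
                        dtype=np.int64)

    def degrees(self) -> dict[int, int]:
        deg = {int(i): 0 for i in self.node_ids}
        for a, b in self.edges.tolist():
            deg[a] += 1
            deg[b] += 1
        return deg

    def nodes_with_tag(self, tag: str) -> np.ndarray:
        """Node ids carrying the given annotation tag."""
        return np.array(sorted(i for i, tags in self.annotations.items()
                               if tag in tags), dtype=np.int64)

    def positions_of(self, node_ids) -> np.ndarray:
        idx = [self._id_to_index[int(i)] for i in np.atleast_1d(node_ids)]
        return self.positions[idx]

    def transformed(self, fn) -> "Skeleton":
        """New skeleton with positions mapped through ``fn`` (topology kept)."""
        return Skeleton(self.tree_id, self.node_ids, fn(self.positions),
                        self.edges, self.radii, self.annotations, self.name,
                        validate=False)


def dedupe_edges(edges: np.ndarray) -> np.ndarray:
    """Explicit repair utility: drop exact duplicate (unordered) edges."""
    seen, out = set(), []
    for a, b in np.asarray(edges, dtype=np.int64).reshape(-1, 2).tolist():
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            out.append((a, b))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def path_length(skeleton: Skeleton) -> float:
    """Total path length in nm: sum of Euclidean lengths over all edges.

    A single-node tree has length 0.
    """
    ei = skeleton.edge_indices
    if not len(ei):
        return 0.0
    d = skeleton.positions[ei[:, 0]] - skeleton.positions[ei[:, 1]]
    return float(np.sqrt((d * d).sum(axis=1)).sum())


def pathlength_histogram(skeletons, bin_width: float):
    """Histogram of per-skeleton path lengths plus cumulative axon fraction.

    Returns a dict with bin edges (nm), counts, the cumulative fraction of
    axons per bin, and the median length (None for empty input).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lengths = np.array([path_length(s) for s in skeletons], dtype=float)
    if len(lengths) == 0:
        return {"lengths_nm": lengths, "bin_edges_nm": np.array([0.0]),
                "counts": np.array([], dtype=int),
                "cumulative_fraction": np.array([]), "median_nm": None,
                "n": 0}
    n_bins = max(1, int(np.ceil(lengths.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    # right-closed bins (a, a + bin_width]: a length on a bin edge counts in
    # the lower bin, so whole-bin-width lengths land one per bin
    idx = np.clip(np.ceil(lengths / bin_width).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    cum = np.cumsum(counts) / len(lengths)
    return {"lengths_nm": lengths, "bin_edges_nm": edges, "counts": counts,
            "cumulative_fraction": cum,
            "median_nm": float(np.median(lengths)), "n": len(lengths)}


def resample_polyline(skeleton: Skeleton, spacing: float) -> Skeleton:
    """Subdivide every edge so that no output edge is longer than ``spacing``.

    All original nodes (hence every branch and end node) are preserved, and
    path length is preserved exactly because subdivision points lie on the
    original segments.  Idempotent on skeletons that are already dense.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    ei = skeleton.edge_indices
    if not len(ei):
        return skeleton
    pos = skeleton.positions
    new_positions = [pos]
    new_edges = []
    next_id = int(skeleton.node_ids.max()) + 1
    new_ids = [skeleton.node_ids]
    for (ia, ib), (a, b) in zip(ei.tolist(), skeleton.edges.tolist()):
        pa, pb = pos[ia], pos[ib]
        seg = np.linalg.norm(pb - pa)
        n_sub = max(1, int(np.ceil(seg / spacing - 1e-12)))
        if n_sub == 1:
            new_edges.append((a, b))
            continue
        t = np.arange(1, n_sub)[:, None] / n_sub
        mids = pa + t * (pb - pa)
        ids = np.arange(next_id, next_id + n_sub - 1)
        next_id += n_sub - 1
        new_positions.append(mids)
        new_ids.append(ids)
        chain = [a] + ids.tolist() + [b]
        new_edges.extend(zip(chain[:-1], chain[1:]))
    radii = None
    if skeleton.radii is not None:
        # new nodes inherit no radius information; pad with NaN
        pad = np.full(next_id - int(skeleton.node_ids.max()) - 1, np.nan)
        radii = np.concatenate([skeleton.radii, pad])
    return Skeleton(skeleton.tree_id, np.concatenate(new_ids),
                    np.vstack(new_positions), np.array(new_edges),
                    radii, skeleton.annotations, skeleton.name,
                    validate=False)


def nodes_in_bbox(skeleton: Skeleton, box: BBox) -> set[int]:
    """Node ids inside the closed box (boundary nodes count)."""
    mask = box.contains(skeleton.positions)
    return set(skeleton.node_ids[mask].tolist())


class SkeletonForestIndex:
    """KD-tree over the pooled nodes of a skeleton collection.

    Query results are contractually identical to an exhaustive scan with a
    closed-ball convention.
    """

    def __init__(self, skeletons):
        self.skeletons = list(skeletons)
        owners, node_ids, chunks = [], [], []
        for k, s in enumerate(self.skeletons):
            if len(s) == 0:
                continue
            owners.append(np.full(len(s), k))
            node_ids.append(s.node_ids)
            chunks.append(s.positions)
        if chunks:
            self._owners = np.concatenate(owners)
            self._node_ids = np.concatenate(node_ids)
            self._tree = cKDTree(np.vstack(chunks))
        else:
            self._owners = np.empty(0, dtype=int)
            self._node_ids = np.empty(0, dtype=np.int64)
            self._tree = None

    def radius_query(self, point, r: float) -> set[tuple[int, int]]:
        """All (skeleton_id, node_id) with node within closed distance r."""
        if r <= 0:
            raise ValueError("r must be > 0")
        if self._tree is None:
            return set()
        idx = self._tree.query_ball_point(np.asarray(point, dtype=float), r)
        return {(self.skeletons[self._owners[i]].tree_id,
                 int(self._node_ids[i])) for i in idx}


def radius_query(skeletons, point, r: float) -> set[tuple[int, int]]:
    """Convenience one-shot wrapper around :class:`SkeletonForestIndex`."""
    return SkeletonForestIndex(skeletons).radius_query(point, r)
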