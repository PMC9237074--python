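"""Marker detection on vertex-colored meshes.

Colored clay disks (or stickers) marking sensor positions are segmented by
manually-chosen HSV ranges, grouped by single-linkage clustering at the marker
scale (nodes closer than the marker diameter belong to one marker), and each
cluster's centre of mass becomes the estimated sensor position, optionally
snapped to the nearest scalp node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .mesh_core import SensorSet, TriangleMesh, nearest_node


@dataclass
class HSVRange:
    """Inclusive HSV box; a hue interval with ``h_lo > h_hi`` wraps through 0."""

    name: str
    h_lo: float
    h_hi: float
    s_lo: float = 0.0
    s_hi: float = 1.0
    v_lo: float = 0.0
    v_hi: float = 1.0

    def __post_init__(self):
        for h in (self.h_lo, self.h_hi):
            if not 0 <= h < 1:
                raise ValueError("hue bounds must lie in [0, 1)")
        for x in (self.s_lo, self.s_hi, self.v_lo, self.v_hi):
            if not 0 <= x <= 1:
                raise ValueError("saturation/value bounds must lie in [0, 1]")
        if self.s_lo > self.s_hi or self.v_lo > self.v_hi:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
        if self.h_lo <= self.h_hi:
            hue_ok = (h >= self.h_lo) & (h <= self.h_hi)
        else:  # interval crosses 0
            hue_ok = (h >= self.h_lo) | (h <= self.h_hi)
        return (
            hue_ok
            & (s >= self.s_lo)
            & (s <= self.s_hi)
            & (v >= self.v_lo)
            & (v <= self.v_hi)
        )


#: HSV ranges for the marker colors used by default on synthetic phantoms.
DEFAULT_HSV_RANGES = [
    HSVRange("red", h_lo=0.95, h_hi=0.05, s_lo=0.5, v_lo=0.3),
    HSVRange("green", h_lo=0.25, h_hi=0.42, s_lo=0.5, v_lo=0.3),
    HSVRange("blue", h_lo=0.58, h_hi=0.75, s_lo=0.5, v_lo=0.3),
    HSVRange("yellow", h_lo=0.12, h_hi=0.22, s_lo=0.5, v_lo=0.3),
]


@dataclass
class ClusterParams:
    """Single-linkage distance (the marker diameter) and speckle rejection."""

    link_dist_mm: float = 3.0
    min_cluster_nodes: int = 3

    def __post_init__(self):
        if self.link_dist_mm <= 0:
            raise ValueError("link_dist_mm must be positive")
        if self.min_cluster_nodes < 1:
            raise ValueError("min_cluster_nodes must be >= 1")


@dataclass
class DetectedMarker:
    color_name: str
    centroid: np.ndarray
    node_indices: list[int] = field(default_factory=list)
    label: str | None = None

    @property
    def node_count(self) -> int:
        return len(self.node_indices)


def rgb_to_hsv(color: np.ndarray) -> np.ndarray:
    """Hexcone RGB -> HSV conversion, all channels in [0, 1] (hue in [0, 1))."""
    color = np.asarray(color, dtype=float)
    if color.ndim != 2 or color.shape[1] != 3:
        raise ValueError("color must be an (N, 3) array")
    if color.size and (color.min() < 0 or color.max() > 1):
        raise ValueError("RGB channels must lie in [0, 1]")
    return _mpl_rgb_to_hsv(color)


def select_by_hsv(mesh: TriangleMesh, hsv_range: HSVRange) -> np.ndarray:
    """Indices of mesh vertices whose color falls inside the HSV box."""
    if mesh.color is None:
        raise ValueError("mesh has no per-vertex color")
    hsv = rgb_to_hsv(mesh.color)
    return np.flatnonzero(hsv_range.contains(hsv))


def cluster_nodes(points: np.ndarray, params: ClusterParams) -> list[list[int]]:
    """Single-linkage clusters: connected components of the < link_dist graph.

    Clusters smaller than ``min_cluster_nodes`` are discarded; the rest are
    ordered by descending size, then by smallest member index.  Returned
    indices are positions into ``points``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    k = len(points)
    if k == 0:
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(params.link_dist_mm, output_type="ndarray")
    if len(pairs):
        # KDTree uses <= r; the linkage rule is strict '<'
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < params.link_dist_mm]
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])) if len(pairs) else ([], ([], [])),
        shape=(k, k),
    )
    _, labels = connected_components(graph, directed=False)
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    out = [c for c in clusters.values() if len(c) >= params.min_cluster_nodes]
    out.sort(key=lambda c: (-len(c), min(c)))
    return out


def detect_markers(
    mesh: TriangleMesh,
    ranges: list[HSVRange] | None = None,
    params: ClusterParams | None = None,
) -> list[DetectedMarker]:
    """Detect colored markers: HSV selection, clustering, centre of mass.

    Each HSV range is processed in list order; a node matched by several
    ranges is assigned to the first and a warning is emitted.  Markers are
    labelled ``<color_name>-<k>`` by cluster order within each color.
    """
    if ranges is None:
        ranges = DEFAULT_HSV_RANGES
    if params is None:
        params = ClusterParams()
    if mesh.color is None:
        raise ValueError("mesh has no per-vertex color")
    claimed = np.zeros(mesh.n_vertices, dtype=bool)
    markers: list[DetectedMarker] = []
    for r in ranges:
        sel = select_by_hsv(mesh, r)
        overlap = claimed[sel]
        if overlap.any():
            warnings.warn(
                f"{int(overlap.sum())} node(s) matched by range {r.name!r} were "
                "already claimed by an earlier range",
                stacklevel=2,
            )
            sel = sel[~overlap]
        if len(sel) == 0:
            continue
        claimed[sel] = True
        for k, cluster in enumerate(cluster_nodes(mesh.vertices[sel], params), start=1):
            nodes = [int(sel[i]) for i in cluster]
            centroid = mesh.vertices[nodes].mean(axis=0)
            markers.append(
                DetectedMarker(
                    color_name=r.name,
                    centroid=centroid,
                    node_indices=nodes,
                    label=f"{r.name}-{k}",
                )
            )
    return markers


def project_markers(markers: list[DetectedMarker], scalp: TriangleMesh) -> SensorSet:
    """Snap marker centroids to the nearest scalp node, binding node indices."""
    if not markers:
        return SensorSet([], np.empty((0, 3)))
    labels = [getattr(m, "label", f"{m.color_name}-{i + 1}") for i, m in enumerate(markers)]
    hits = nearest_node(scalp, np.stack([m.centroid for m in markers]))
    positions = np.stack([scalp.vertices[i] for i, _ in hits])
    return SensorSet(labels, positions, [i for i, _ in hits])
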