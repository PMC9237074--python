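"""Surface-mesh data model, file I/O and mesh-conditioning operators.

All coordinates are millimetres in a right-handed frame.  No anatomical axis
convention is assumed from files: a :class:`HeadFrame` derived from cranial
landmarks (nasion, preauricular points) defines the right/anterior/superior
directions wherever an operation needs them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    ConvergenceError,
    DegenerateGeometryError,
    EmptyResultError,
    MeshFormatError,
)

LANDMARK_NAMES = ("nasion", "inion", "Cz", "LPA", "RPA")


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangle surface mesh with optional per-vertex RGB color.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    faces : (M, 3) int array, vertex indices
    color : (N, 3) float array in [0, 1], optional
    """

    vertices: np.ndarray
    faces: np.ndarray
    color: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (M, 3) array")
        if len(self.vertices) < 3 or len(self.faces) < 1:
            raise MeshFormatError("mesh needs at least 3 vertices and 1 face")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("vertices contain non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshFormatError("face indices out of range")
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=float)
            if self.color.shape != (len(self.vertices), 3):
                raise MeshFormatError("color must be an (N, 3) array")
            if self.color.min() < 0 or self.color.max() > 1:
                raise MeshFormatError("color channels must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def mean_edge_length(self) -> float:
        e = self.vertices[self.faces]
        d = np.concatenate(
            [
                np.linalg.norm(e[:, 0] - e[:, 1], axis=1),
                np.linalg.norm(e[:, 1] - e[:, 2], axis=1),
                np.linalg.norm(e[:, 2] - e[:, 0], axis=1),
            ]
        )
        return float(d.mean())

    def submesh(self, keep: np.ndarray) -> "TriangleMesh":
        """Sub-mesh of the vertices flagged in boolean mask ``keep``.

        Faces survive only if all three corners survive; vertex indices are
        compacted; colors are carried along.
        """
        keep = np.asarray(keep, dtype=bool)
        if not keep.any():
            raise EmptyResultError("no vertices survive the selection")
        new_index = -np.ones(len(self.vertices), dtype=np.int64)
        new_index[keep] = np.arange(int(keep.sum()))
        fkeep = keep[self.faces].all(axis=1)
        if not fkeep.any():
            raise EmptyResultError("no faces survive the selection")
        return TriangleMesh(
            vertices=self.vertices[keep],
            faces=new_index[self.faces[fkeep]],
            color=None if self.color is None else self.color[keep],
        )

    def as_trimesh(self) -> trimesh.Trimesh:
        kw = {}
        if self.color is not None:
            rgba = np.empty((self.n_vertices, 4), dtype=np.uint8)
            rgba[:, :3] = np.rint(self.color * 255).astype(np.uint8)
            rgba[:, 3] = 255
            kw["vertex_colors"] = rgba
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False, **kw)


@dataclass
class PointSet:
    """Unstructured point cloud (output of :func:`downsample_grid`)."""

    points: np.ndarray
    color: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


class LandmarkSet(Mapping):
    """Named cranial fiducials (subset of nasion/inion/Cz/LPA/RPA), mm."""

    def __init__(self, coords: Mapping[str, Sequence[float]]):
        self._coords: dict[str, np.ndarray] = {}
        for name, xyz in coords.items():
            if name not in LANDMARK_NAMES:
                raise ValueError(
                    f"unknown landmark {name!r}; allowed: {LANDMARK_NAMES}"
                )
            p = np.asarray(xyz, dtype=float).reshape(3)
            if not np.isfinite(p).all():
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            self._coords[name] = p

    def __getitem__(self, name: str) -> np.ndarray:
        return self._coords[name]

    def __iter__(self):
        return iter(self._coords)

    def __len__(self) -> int:
        return len(self._coords)

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self._coords]
        if missing:
            raise ValueError(f"missing landmark(s): {', '.join(missing)}")

    def array(self, names: Iterable[str]) -> np.ndarray:
        self.require(names)
        return np.stack([self._coords[n] for n in names])

    def transformed(self, func) -> "LandmarkSet":
        names = list(self._coords)
        pts = func(np.stack([self._coords[n] for n in names]))
        return LandmarkSet(dict(zip(names, pts)))

    def to_csv(self, path) -> None:
        rows = [(n, *self._coords[n]) for n in self._coords]
        pd.DataFrame(rows, columns=["label", "x", "y", "z"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls({r.label: (r.x, r.y, r.z) for r in df.itertuples()})


class SensorSet:
    """Ordered, labelled 3D sensor positions, optionally bound to mesh nodes."""

    def __init__(
        self,
        labels: Sequence[str],
        positions: np.ndarray,
        node_indices: Sequence[int | None] | None = None,
    ):
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")
        self.positions = np.asarray(positions, dtype=float).reshape(len(self.labels), 3)
        self.node_indices = (
            list(node_indices) if node_indices is not None else [None] * len(self.labels)
        )
        if len(self.node_indices) != len(self.labels):
            raise ValueError("node_indices length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(zip(self.labels, self.positions, self.node_indices))

    def transformed(self, func) -> "SensorSet":
        return SensorSet(self.labels, func(self.positions))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "label": self.labels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorSet":
        df = pd.read_csv(path)
        return cls(df["label"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy(float))


@dataclass
class DownsampleParams:
    """Box-grid downsampling target (the study used ~3000 and ~9000 nodes)."""

    target_nodes: int = 3000
    tolerance_frac: float = 0.10

    def __post_init__(self):
        if self.target_nodes < 4:
            raise ValueError("target_nodes must be >= 4")
        if not 0 < self.tolerance_frac < 1:
            raise ValueError("tolerance_frac must be in (0, 1)")


@dataclass
class HeadFrame:
    """Anatomical frame: origin plus right/anterior/superior unit axes (rows)."""

    origin: np.ndarray
    axes: np.ndarray  # rows: right, anterior, superior

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed (det +1)")

    def superior_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate of ``points`` along the superior axis, mm."""
        return (np.atleast_2d(points) - self.origin) @ self.axes[2]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_mesh(path) -> TriangleMesh:
    """Read a PLY or OBJ surface mesh, preserving per-vertex color if present.

    Units are taken as millimetres as stored.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of types
        raise MeshFormatError(f"cannot read mesh {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} does not contain a triangle mesh")
    color = None
    if getattr(tm.visual, "kind", None) == "vertex":
        color = np.asarray(tm.visual.vertex_colors[:, :3], dtype=float) / 255.0
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.size and (faces.min() < 0 or faces.max() >= len(tm.vertices)):
        raise MeshFormatError(f"{path}: faces reference missing vertices")
    return TriangleMesh(np.asarray(tm.vertices, float), faces, color)


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as PLY (ASCII, with colors when present) or OBJ.

    The file round-trips through :func:`read_mesh` with vertices equal to at
    least six decimal places and colors within 1/255 per channel.
    """
    path = Path(path)
    tm = mesh.as_trimesh()
    try:
        if path.suffix.lower() == ".ply":
            # ASCII keeps float64 precision; trimesh's binary PLY is float32
            tm.export(str(path), encoding="ascii")
        else:
            tm.export(str(path), include_color=mesh.color is not None)
    except OSError:
        raise
    except Exception as exc:
        raise IOError(f"cannot write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# head frame and plane cut
# ---------------------------------------------------------------------------


def head_frame_from_landmarks(lm: LandmarkSet) -> HeadFrame:
    """Anatomical frame from nasion and the two preauricular points.

    Origin is the LPA/RPA midpoint; right axis along RPA-LPA; anterior axis is
    the nasion direction orthogonalized against it; superior axis completes the
    right-handed triad.
    """
    lm.require(["nasion", "LPA", "RPA"])
    lpa, rpa, nas = lm["LPA"], lm["RPA"], lm["nasion"]
    origin = 0.5 * (lpa + rpa)
    right = rpa - lpa
    nr = np.linalg.norm(right)
    if nr < 1e-9:
        raise DegenerateGeometryError("LPA and RPA coincide")
    right = right / nr
    anterior = nas - origin
    anterior = anterior - (anterior @ right) * right
    na = np.linalg.norm(anterior)
    if na < 1e-9:
        raise DegenerateGeometryError("nasion collinear with the ear axis")
    anterior = anterior / na
    superior = np.cross(right, anterior)
    return HeadFrame(origin, np.stack([right, anterior, superior]))


def cut_below_plane(mesh: TriangleMesh, frame: HeadFrame, level_mm: float) -> TriangleMesh:
    """Keep the part of ``mesh`` at or above an axial plane.

    Vertices with superior-axis coordinate >= ``level_mm`` survive, along with
    faces whose three corners all survive; indices are compacted.
    """
    s = frame.superior_coordinate(mesh.vertices)
    return mesh.submesh(s >= level_mm)


def cut_points_below_plane(
    points: np.ndarray, frame: HeadFrame, level_mm: float
) -> np.ndarray:
    """Point-set analogue of :func:`cut_below_plane`."""
    points = np.atleast_2d(points)
    keep = frame.superior_coordinate(points) >= level_mm
    if not keep.any():
        raise EmptyResultError("no points survive the plane cut")
    return points[keep]


# ---------------------------------------------------------------------------
# downsampling, smoothing, nearest node
# ---------------------------------------------------------------------------


def _box_grid_reduce(vertices, color, edge):
    """Average vertices (and colors) per occupied cubic box of size ``edge``."""
    lo = vertices.min(axis=0)
    idx = np.floor((vertices - lo) / edge).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    k = len(counts)
    pts = np.zeros((k, 3))
    np.add.at(pts, inverse, vertices)
    pts /= counts[:, None]
    col = None
    if color is not None:
        col = np.zeros((k, 3))
        np.add.at(col, inverse, color)
        col /= counts[:, None]
    return pts, col


def _box_count(vertices, edge):
    lo = vertices.min(axis=0)
    idx = np.floor((vertices - lo) / edge).astype(np.int64)
    return len(np.unique(idx, axis=0))


def downsample_grid(mesh: TriangleMesh | PointSet, params: DownsampleParams) -> PointSet:
    """Box-grid (voxel) downsampling to approximately ``target_nodes`` points.

    Space is partitioned into cubic boxes of one edge length; each occupied box
    contributes the mean of its vertices (colors averaged likewise).  The edge
    length is found by bisection so that the output count falls within
    ``tolerance_frac`` of the target.  Face structure is not preserved.
    """
    vertices = mesh.points if isinstance(mesh, PointSet) else mesh.vertices
    color = mesh.color
    n = len(vertices)
    target = params.target_nodes
    if target >= n:
        raise ValueError(f"target_nodes ({target}) must be < vertex count ({n})")
    tol_lo = int(np.ceil(target * (1 - params.tolerance_frac)))
    tol_hi = int(np.floor(target * (1 + params.tolerance_frac)))

    span = vertices.max(axis=0) - vertices.min(axis=0)
    hi = float(np.linalg.norm(span)) + 1e-9  # one box: count = 1
    lo = hi / n ** (1 / 3) / 64  # fine grid: count ~ n
    best_edge, best_count = hi, 1
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = _box_count(vertices, mid)
        if abs(c - target) < abs(best_count - target):
            best_edge, best_count = mid, c
        if tol_lo <= c <= tol_hi:
            pts, col = _box_grid_reduce(vertices, color, mid)
            return PointSet(pts, col)
        if c > target:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError(
        f"box-grid bisection did not reach {target}±{params.tolerance_frac:.0%} "
        f"in 60 iterations (best count: {best_count})",
        best=best_count,
    )


def smooth_lowpass(
    mesh: TriangleMesh, iterations: int = 10, lamb: float = 0.5, nu: float = 0.53
) -> TriangleMesh:
    """Two-factor (shrink/inflate) Laplacian low-pass smoothing.

    Alternates a shrinking Laplacian step of weight ``lamb`` with an inflating
    step of weight ``-nu`` (Taubin scheme), which keeps the enclosed volume of
    a closed mesh within ~2% at the defaults.  Connectivity and colors are
    unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(), None if mesh.color is None else mesh.color.copy())
    tm = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces.copy(), process=False)
    trimesh.smoothing.filter_taubin(tm, lamb=lamb, nu=nu, iterations=iterations)
    v = np.asarray(tm.vertices, float)
    if not np.isfinite(v).all():
        raise ArithmeticError("smoothing produced non-finite vertices")
    return TriangleMesh(v, mesh.faces.copy(), None if mesh.color is None else mesh.color.copy())


def nearest_node(
    mesh: TriangleMesh | PointSet, points: np.ndarray
) -> list[tuple[int, float]]:
    """Nearest mesh vertex (index, distance in mm) for each query point.

    Ties are broken by the lowest vertex index.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return []
    points = np.atleast_2d(points)
    verts = mesh.points if isinstance(mesh, PointSet) else mesh.vertices
    tree = cKDTree(verts)
    dist, idx = tree.query(points)
    out = []
    for p, d, i in zip(points, dist, idx):
        # deterministic tie-break: lowest index among equidistant vertices
        cand = tree.query_ball_point(p, d + 1e-9)
        cand = [j for j in cand if abs(np.linalg.norm(verts[j] - p) - d) <= 1e-9]
        j = min(cand) if cand else int(i)
        out.append((int(j), float(np.linalg.norm(verts[j] - p))))
    return out
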