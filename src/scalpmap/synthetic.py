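"""Synthetic inputs with known ground truth.

Digital stand-ins for the physical ingredients of a scalp-sensor study: an
ellipsoidal head "phantom" carrying colored marker disks at 10-20-family
layout positions, randomly deformed "subjects" derived from an atlas head
with an exactly known forward mapping, and smooth fluence-like scalar fields.

The 10-20-family layout is built from arc fractions on the unit sphere
(midline meridian, the 10% ring, and interior coronal rows) and mapped to the
ellipsoid; the position counts this construction yields are recorded in
:data:`LAYOUT_COUNTS`, the single source of truth for expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import LayoutDensityError
from .evaluation import ScalarField
from .mesh_core import LandmarkSet, SensorSet, TriangleMesh
from .registration import AffineTransform, NonrigidWarp

MARKER_RGB = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
}

_LAYOUT_STEP = {"10-20": 0.2, "10-10": 0.1, "10-5": 0.05}

#: positions generated per named layout by this module's construction
LAYOUT_COUNTS = {"10-20": 21, "10-10": 69, "10-5": 261}

_MARGIN = 0.1  # lowest arc fraction used (the "10%" of 10-20)

#: Head-shape features as (unit direction, radial amplitude fraction, angular
#: width in radians).  A pure ellipsoid is affinely self-similar (any
#: S2·R·S1^-1 maps one ellipsoid exactly onto another), so surface-to-surface
#: registration on it cannot identify a planted transform; real heads are not
#: ellipsoids.  These deterministic bumps — a nose, brow and occipital
#: protrusions and slightly asymmetric parietal features — give the phantom a
#: few-millimetre head-like deviation from the ellipsoid.
DEFAULT_HEAD_FEATURES = (
    ((0.0, 0.9, -0.45), 0.18, 0.22),  # nose (below the nasion plane)
    ((0.0, 0.95, 0.25), 0.04, 0.30),  # brow ridge
    ((0.0, -0.95, 0.25), 0.06, 0.30),  # occipital protrusion
    ((0.6, -0.4, 0.65), 0.03, 0.35),  # right parietal
    ((-0.5, 0.45, 0.6), 0.02, 0.35),  # left fronto-parietal
)


def _radius_factor(directions: np.ndarray, features) -> np.ndarray:
    """Radial modulation of unit-sphere directions by Gaussian angular bumps."""
    directions = np.atleast_2d(directions)
    r = np.ones(len(directions))
    for center, amp, width in features:
        c = np.asarray(center, float)
        c = c / np.linalg.norm(c)
        ang = np.arccos(np.clip(directions @ c, -1.0, 1.0))
        r += amp * np.exp(-(ang**2) / (2.0 * width**2))
    return r


@dataclass
class PhantomSpec:
    """Ellipsoidal head phantom with colored marker disks at layout positions.

    Default semi-axes approximate an adult head (right-left, posterior-
    anterior, inferior-superior); the default 5 mm disk matches a clay marker
    on a cap (a printed-phantom hollow would be 3 mm).
    """

    seed: int = 0
    axes_mm: tuple[float, float, float] = (98.0, 134.0, 110.0)
    subdivisions: int = 6
    marker_diameter_mm: float = 5.0
    layout: str | list = "10-10"
    colors: tuple[str, ...] = ("red", "green", "blue", "yellow")
    background_color: tuple[float, float, float] = (0.0, 0.0, 0.0)
    paint_markers: bool = True
    min_nodes_per_marker: int = 3
    lower_cut_frac: float = 0.6  # keep directions with z >= -lower_cut_frac
    features: tuple = DEFAULT_HEAD_FEATURES

    def __post_init__(self):
        if min(self.axes_mm) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.marker_diameter_mm <= 0:
            raise ValueError("marker_diameter_mm must be positive")


@dataclass
class DeformationSpec:
    """Random subject-from-atlas deformation: affine, smooth warp, noise.

    The affine part draws per-axis scales, a rotation and shears within the
    stated bounds (about the head centroid, no translation); the non-rigid
    part sums Gaussian displacement kernels anchored at random surface points;
    per-vertex isotropic noise emulates reconstruction error and perturbs the
    mesh only (landmarks/sensors are carried through the noise-free map).
    """

    seed: int = 0
    scale_range: tuple[float, float] = (0.93, 1.07)
    max_rotation_deg: float = 15.0
    max_shear: float = 0.08
    nonrigid_amp_mm: float = 4.0
    nonrigid_centers: int = 12
    nonrigid_width_mm: float = 40.0
    noise_sigma_mm: float = 0.0

    def __post_init__(self):
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("invalid scale_range")
        if self.nonrigid_width_mm <= 0 or self.nonrigid_centers < 1:
            raise ValueError("invalid non-rigid kernel parameters")
        if self.noise_sigma_mm < 0 or self.nonrigid_amp_mm < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class SubjectMap:
    """Exactly known atlas -> subject forward mapping (affine then warp)."""

    affine: AffineTransform
    warp: NonrigidWarp

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.warp.apply(self.affine.apply(points))


def _substream(seed: int, stage: int) -> np.random.Generator:
    # one named substream per stage: adding a stage never perturbs earlier draws
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), stage]))


# ---------------------------------------------------------------------------
# layout construction on the unit sphere
# ---------------------------------------------------------------------------


def _sagittal(f: float) -> np.ndarray:
    """Midline meridian, nasion (f=0) over the apex to inion (f=1)."""
    return np.array([0.0, np.cos(np.pi * f), np.sin(np.pi * f)])


def _ring(g: float, side: int) -> np.ndarray:
    """The 10% ring; g runs front (0) to back (1), side +1 right / -1 left."""
    z0 = np.sin(np.pi * _MARGIN)
    r0 = np.cos(np.pi * _MARGIN)
    return np.array([side * r0 * np.sin(np.pi * g), r0 * np.cos(np.pi * g), z0])


def _circle_arc(a: np.ndarray, m: np.ndarray, b: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Points at arc fractions ``ts`` along the circle a -> m -> b (on-sphere)."""
    u, v = m - a, b - a
    n = np.cross(u, v)
    nn = np.dot(n, n)
    if nn < 1e-15:
        raise ValueError("arc endpoints are collinear")
    center = a + np.cross(np.dot(u, u) * v - np.dot(v, v) * u, n) / (2.0 * nn)
    e1 = a - center
    rho = np.linalg.norm(e1)
    e1 = e1 / rho
    for e2 in (np.cross(n / np.sqrt(nn), e1), -np.cross(n / np.sqrt(nn), e1)):
        th_m = np.arctan2(np.dot(m - center, e2), np.dot(m - center, e1)) % (2 * np.pi)
        th_b = np.arctan2(np.dot(b - center, e2), np.dot(b - center, e1)) % (2 * np.pi)
        if 0 < th_m < th_b:
            angles = ts * th_b
            return center + rho * (
                np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
            )
    raise ValueError("could not orient arc")


def layout_positions(layout: str | list) -> tuple[list[str], np.ndarray]:
    """Labels and unit-sphere positions for a named or custom layout.

    Custom layouts are lists of ``(label, unit_vector)`` pairs.  Named layouts
    use fraction step 0.2 / 0.1 / 0.05 for 10-20 / 10-10 / 10-5 with a 10%
    margin, giving the counts in :data:`LAYOUT_COUNTS`.
    """
    if isinstance(layout, list):
        labels = [lab for lab, _ in layout]
        pts = np.array([np.asarray(p, float) / np.linalg.norm(p) for _, p in layout])
        return labels, pts
    if layout not in _LAYOUT_STEP:
        raise ValueError(f"unknown layout {layout!r}")
    step = _LAYOUT_STEP[layout]
    fracs = np.round(np.arange(_MARGIN, 0.9 + 1e-9, step), 10)
    labels: list[str] = []
    pts: list[np.ndarray] = []
    for f in fracs:  # midline
        labels.append(f"mid-{round(f * 100)}")
        pts.append(_sagittal(f))
    for g in fracs:  # the 10% ring, both sides
        for side, tag in ((1, "R"), (-1, "L")):
            labels.append(f"ring-{tag}-{round(g * 100)}")
            pts.append(_ring(g, side))
    n_row = len(fracs)
    ts = np.linspace(0.0, 1.0, n_row)
    mid_j = (n_row - 1) // 2
    for g in fracs[1:-1]:  # interior coronal rows, left ring -> midline -> right
        row = _circle_arc(_ring(g, -1), _sagittal(g), _ring(g, 1), ts)
        for j in range(1, n_row - 1):
            if j == mid_j:
                continue  # midline point already placed
            frac_lr = round(ts[j] * 100)
            labels.append(f"row-{round(g * 100)}-{'L' if j < mid_j else 'R'}{frac_lr}")
            pts.append(row[j])
    return labels, np.array(pts)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec) -> tuple[TriangleMesh, LandmarkSet, SensorSet]:
    """Ellipsoidal scalp mesh, landmarks, and ground-truth marker positions.

    Landmarks sit at the ellipsoid's anatomical extremes; layout positions are
    painted as colored disks (color cycled through ``spec.colors``) on an
    otherwise background-colored surface.  Deterministic for a given spec.
    """
    a, b, c = spec.axes_mm
    axes = np.array([a, b, c])
    sphere = trimesh.creation.icosphere(subdivisions=spec.subdivisions)
    dirs = np.asarray(sphere.vertices, float)
    verts = dirs * _radius_factor(dirs, spec.features)[:, None] * axes
    mesh = TriangleMesh(verts, np.asarray(sphere.faces, dtype=np.int64))
    mesh = mesh.submesh(dirs[:, 2] >= -spec.lower_cut_frac)

    def on_surface(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        return u * _radius_factor(u, spec.features)[:, None] * axes

    lm_dirs = {
        "nasion": (0.0, 1.0, 0.0),
        "inion": (0.0, -1.0, 0.0),
        "LPA": (-1.0, 0.0, 0.0),
        "RPA": (1.0, 0.0, 0.0),
        "Cz": (0.0, 0.0, 1.0),
    }
    lm = LandmarkSet({k: on_surface(np.array(v))[0] for k, v in lm_dirs.items()})

    labels, sphere_pts = layout_positions(spec.layout)
    centers = on_surface(sphere_pts)

    radius = spec.marker_diameter_mm / 2.0
    if len(centers) > 1:
        tree_c = cKDTree(centers)
        dmin, _ = tree_c.query(centers, k=2)
        if dmin[:, 1].min() < spec.marker_diameter_mm:
            raise LayoutDensityError(
                f"marker spacing {dmin[:, 1].min():.2f} mm is below the marker "
                f"diameter {spec.marker_diameter_mm} mm"
            )

    color = np.tile(np.asarray(spec.background_color, float), (mesh.n_vertices, 1))
    if spec.paint_markers:
        tree = cKDTree(mesh.vertices)
        for i, center in enumerate(centers):
            nodes = tree.query_ball_point(center, radius)
            if len(nodes) < spec.min_nodes_per_marker:
                raise LayoutDensityError(
                    f"marker {labels[i]!r} covers only {len(nodes)} node(s); "
                    "increase mesh subdivisions or the marker diameter"
                )
            color[nodes] = MARKER_RGB[spec.colors[i % len(spec.colors)]]
    mesh.color = color

    return mesh, lm, SensorSet(labels, centers)


def make_subject(
    atlas: TriangleMesh,
    atlas_lm: LandmarkSet,
    atlas_sensors: SensorSet,
    d: DeformationSpec,
) -> tuple[TriangleMesh, LandmarkSet, SensorSet, SubjectMap]:
    """Random deformed subject with an exactly known atlas->subject mapping.

    Applies, in order: a random affine (scale/rotation/shear about the head
    centroid), a smooth non-rigid displacement (sum of Gaussian kernels), and
    per-vertex noise (mesh only).  Landmarks and sensors are carried through
    the noise-free map, so the correspondence to atlas space is exact.
    """
    centroid = atlas.vertices.mean(axis=0)

    rng_aff = _substream(d.seed, 1)
    scales = rng_aff.uniform(*d.scale_range, size=3)
    axis = rng_aff.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng_aff.uniform(0.0, d.max_rotation_deg))
    rot = Rotation.from_rotvec(axis * angle).as_matrix()
    shear = np.eye(3)
    shear[np.triu_indices(3, 1)] = rng_aff.uniform(-d.max_shear, d.max_shear, size=3)
    lin = rot @ shear @ np.diag(scales)
    affine = AffineTransform(lin, centroid - lin @ centroid)

    rng_nr = _substream(d.seed, 2)
    centers_idx = rng_nr.choice(atlas.n_vertices, size=d.nonrigid_centers, replace=False)
    centers = affine.apply(atlas.vertices[centers_idx])
    dirs = rng_nr.normal(size=(d.nonrigid_centers, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng_nr.uniform(0.0, d.nonrigid_amp_mm, size=d.nonrigid_centers)
    warp = NonrigidWarp(
        control_points=centers,
        kernel_width=d.nonrigid_width_mm,
        weights=dirs * amps[:, None],
    )

    smap = SubjectMap(affine, warp)
    verts = smap.apply(atlas.vertices)
    if d.noise_sigma_mm > 0:
        rng_noise = _substream(d.seed, 3)
        verts = verts + rng_noise.normal(0.0, d.noise_sigma_mm, size=verts.shape)

    subj_mesh = TriangleMesh(
        verts,
        atlas.faces.copy(),
        None if atlas.color is None else atlas.color.copy(),
    )
    subj_lm = atlas_lm.transformed(smap.apply)
    subj_sensors = atlas_sensors.transformed(smap.apply)
    return subj_mesh, subj_lm, subj_sensors, smap


def measure_landmarks(
    lm: LandmarkSet,
    mesh: TriangleMesh,
    sigma_mm: float = 3.0,
    seed: int = 0,
) -> LandmarkSet:
    """Emulate manual landmark identification on a head mesh.

    True landmark positions are perturbed by isotropic identification noise
    (cranial landmarks — the inion above all — are identified by eye, with
    reported variability of several millimetres) and snapped to the nearest
    mesh node, which is how positions are read off a reconstructed surface.
    """
    from .mesh_core import nearest_node  # local import to avoid cycle at import time

    rng = _substream(seed, 4)
    names = list(lm)
    pts = np.stack([lm[n] for n in names])
    pts = pts + rng.normal(0.0, sigma_mm, size=pts.shape)
    hits = nearest_node(mesh, pts)
    return LandmarkSet({n: mesh.vertices[i] for n, (i, _) in zip(names, hits)})


def make_field(mesh: TriangleMesh, center_node: int, width_mm: float) -> ScalarField:
    """Gaussian fluence-like field, value 1 at ``center_node``.

    Values fall off with Euclidean distance from the center vertex:
    ``exp(-d^2 / (2 width^2))``.
    """
    if not 0 <= center_node < mesh.n_vertices:
        raise ValueError("center_node out of range")
    if width_mm <= 0:
        raise ValueError("width_mm must be positive")
    dist2 = ((mesh.vertices - mesh.vertices[center_node]) ** 2).sum(axis=1)
    return ScalarField(np.exp(-dist2 / (2.0 * width_mm**2)))
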