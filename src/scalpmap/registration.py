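"""Point-set and surface registration.

Three families of mappings are estimated here:

* closed-form landmark fits — a least-squares rigid (orthogonal Procrustes,
  reflections excluded) or affine transform between named cranial fiducials;
* iterative closest point (ICP) — rigid refinement by alternating
  nearest-neighbour correspondence and Procrustes updates;
* coherent point drift (CPD) — probabilistic registration in which the moving
  points are the centroids of an isotropic Gaussian mixture (plus a uniform
  outlier component of weight ``omega``) fitted to the fixed points by EM,
  with either an affine transform or a smoothness-regularized non-rigid
  displacement field (Gaussian kernel of width ``beta``, trade-off
  ``lambda_reg``).

ICP and CPD follow a model/results idiom: construct the model from the two
point sets, call :meth:`fit`, and read estimates and per-iteration diagnostics
off the returned results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import mesh_core
from .errors import DegenerateGeometryError, StageError
from .mesh_core import (
    DownsampleParams,
    LandmarkSet,
    PointSet,
    SensorSet,
    TriangleMesh,
    cut_points_below_plane,
    downsample_grid,
    head_frame_from_landmarks,
    nearest_node,
    smooth_lowpass,
)

RIGID_LANDMARKS = ("nasion", "Cz", "LPA", "RPA")
AFFINE_LANDMARKS = ("nasion", "inion", "Cz", "LPA", "RPA")


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation


@dataclass
class AffineTransform:
    """x -> A x + t with A invertible."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) <= 1e-12:
            raise ValueError("linear part must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.linear.T + self.translation


@dataclass
class NonrigidWarp:
    """x -> x + sum_k exp(-|x - y0_k|^2 / (2 beta^2)) w_k (all in mm)."""

    control_points: np.ndarray  # (K, 3)
    kernel_width: float  # beta, mm
    weights: np.ndarray  # (K, 3)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if self.weights.shape != self.control_points.shape:
            raise ValueError("weights/control_points shape mismatch")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        g = np.exp(
            -cdist(points, self.control_points, "sqeuclidean")
            / (2.0 * self.kernel_width**2)
        )
        return g @ self.weights

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return points + self.displacement(points)


Transform = RigidTransform | AffineTransform | NonrigidWarp


def apply_transform(t: Transform, points: np.ndarray) -> np.ndarray:
    """Apply any transform to a (P, 3) array of mm coordinates."""
    return t.apply(points)


def compose(first: Transform, second: Transform):
    """Transform equivalent to applying ``first`` then ``second``.

    Only linear transforms compose in closed form; mixed pipelines involving a
    :class:`NonrigidWarp` are applied sequentially instead.
    """
    if isinstance(first, NonrigidWarp) or isinstance(second, NonrigidWarp):
        raise TypeError("non-rigid warps do not compose in closed form")
    a1 = first.rotation if isinstance(first, RigidTransform) else first.linear
    t1 = first.translation
    a2 = second.rotation if isinstance(second, RigidTransform) else second.linear
    t2 = second.translation
    if isinstance(first, RigidTransform) and isinstance(second, RigidTransform):
        return RigidTransform(a2 @ a1, a2 @ t1 + t2)
    return AffineTransform(a2 @ a1, a2 @ t1 + t2)


# ---------------------------------------------------------------------------
# landmark fits
# ---------------------------------------------------------------------------


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit (reflection excluded) of src onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    s, d = src - mu_s, dst - mu_d
    h = s.T @ d
    u, sv, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    return RigidTransform(r, mu_d - r @ mu_s)


def rigid_from_landmarks(
    src: LandmarkSet, dst: LandmarkSet, names: tuple[str, ...] = RIGID_LANDMARKS
) -> RigidTransform:
    """Rigid Procrustes fit between named landmarks of two heads.

    The default landmark set {nasion, Cz, LPA, RPA} omits the inion, the
    hardest fiducial to identify reliably.
    """
    a, b = src.array(names), dst.array(names)
    if len(a) < 3:
        raise ValueError("at least 3 landmarks are required")
    sv = np.linalg.svd(a - a.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("landmarks are collinear")
    return _kabsch(a, b)


def affine_from_landmarks(
    src: LandmarkSet, dst: LandmarkSet, names: tuple[str, ...] = AFFINE_LANDMARKS
) -> AffineTransform:
    """Least-squares affine fit from the five cranial landmarks.

    Exact when ``dst`` is an affine image of ``src``; raises when the source
    landmarks are coplanar (fewer than 4 affinely independent points).
    """
    a, b = src.array(names), dst.array(names)
    hom = np.hstack([a, np.ones((len(a), 1))])
    if np.linalg.matrix_rank(hom, tol=1e-7 * max(np.abs(a).max(), 1.0)) < 4:
        raise DegenerateGeometryError(
            "landmarks are coplanar; affine fit is rank-deficient"
        )
    coef, *_ = np.linalg.lstsq(hom, b, rcond=None)
    return AffineTransform(coef[:3].T, coef[3])


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


@dataclass
class ICPParams:
    max_iter: int = 100
    tol_mm: float = 1e-4

    def __post_init__(self):
        if self.max_iter < 1 or self.tol_mm <= 0:
            raise ValueError("ICP parameters must be positive")


@dataclass
class ICPResult:
    """Rigid ICP estimate with per-iteration mean correspondence distances."""

    transform: RigidTransform
    mean_distances: list[float]
    n_iter: int
    converged: bool

    @property
    def final_mean_distance_mm(self) -> float:
        return self.mean_distances[-1]

    def summary(self) -> str:
        return (
            f"ICP: {self.n_iter} iteration(s), "
            f"mean correspondence distance {self.final_mean_distance_mm:.4g} mm, "
            f"{'converged' if self.converged else 'not converged'}"
        )


class IterativeClosestPoint:
    """Rigid point-to-vertex ICP of a moving set onto a fixed set or mesh."""

    def __init__(self, moving: np.ndarray, fixed: np.ndarray | TriangleMesh):
        self.moving = np.atleast_2d(np.asarray(moving, dtype=float))
        fixed_pts = fixed.vertices if isinstance(fixed, TriangleMesh) else fixed
        self.fixed = np.atleast_2d(np.asarray(fixed_pts, dtype=float))
        if len(self.moving) == 0 or len(self.fixed) == 0:
            raise ValueError("both point sets must be non-empty")
        self._tree = cKDTree(self.fixed)

    def fit(
        self, init: RigidTransform | None = None, params: ICPParams | None = None
    ) -> ICPResult:
        params = params or ICPParams()
        t = init or RigidTransform.identity()
        history: list[float] = []
        converged = False
        for _ in range(params.max_iter):
            y = t.apply(self.moving)
            dist, idx = self._tree.query(y)
            mean_d = float(dist.mean())
            if history and history[-1] - mean_d < params.tol_mm:
                history.append(min(mean_d, history[-1]))
                converged = True
                break
            history.append(mean_d)
            # re-fit from the original moving set: the result is already the
            # composed transform
            t = _kabsch(self.moving, self.fixed[idx])
        return ICPResult(t, history, len(history), converged)


def icp_refine(
    moving: np.ndarray,
    fixed: np.ndarray | TriangleMesh,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
) -> RigidTransform:
    """Functional wrapper around :class:`IterativeClosestPoint`."""
    return IterativeClosestPoint(moving, fixed).fit(init, params).transform


# ---------------------------------------------------------------------------
# CPD
# ---------------------------------------------------------------------------


@dataclass
class CPDParams:
    """CPD parameters; the non-rigid defaults are omega 0.4, lambda 5, beta 4.

    ``omega`` is the weight of the uniform outlier component ("the amount of
    noise in the point set"), ``lambda_reg`` the smoothness trade-off and
    ``beta`` the Gaussian kernel width of the non-rigid displacement field.
    ``lambda_reg``/``beta`` act on internally normalized (unit-RMS)
    coordinates when ``normalize`` is true.
    """

    omega: float = 0.4
    lambda_reg: float = 5.0
    beta: float = 4.0
    max_iter: int = 150
    tol: float = 1e-6
    normalize: bool = True

    def __post_init__(self):
        if not 0 <= self.omega < 1:
            raise ValueError("omega must lie in [0, 1)")
        if self.lambda_reg <= 0 or self.beta <= 0:
            raise ValueError("lambda_reg and beta must be positive")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter and tol must be positive")


@dataclass
class CPDResult:
    """Fitted CPD transform with EM diagnostics."""

    transform: AffineTransform | NonrigidWarp
    mode: str
    sigma2_history: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def sigma2(self) -> float:
        return self.sigma2_history[-1]

    def summary(self) -> str:
        return (
            f"CPD ({self.mode}): {self.n_iter} EM iteration(s), "
            f"final sigma^2 {self.sigma2:.4g}, "
            f"objective {self.objective_history[-1]:.6g}, "
            f"{'converged' if self.converged else 'reached max_iter'}"
        )


class CoherentPointDrift:
    """CPD registration model of a moving point set onto a fixed one.

    The transformed moving points are the centroids of an isotropic Gaussian
    mixture with common variance sigma^2, mixed with a uniform outlier
    component of weight ``omega``; EM alternates posterior correspondence
    probabilities (E-step) with a weighted least-squares update of the
    transform and sigma^2 (M-step).  When ``normalize`` is set both sets are
    jointly centered and scaled to unit RMS internally and the fitted
    transform is mapped back to mm.
    """

    def __init__(
        self,
        moving: np.ndarray,
        fixed: np.ndarray,
        mode: str = "affine",
        params: CPDParams | None = None,
    ):
        if mode not in ("affine", "nonrigid"):
            raise ValueError("mode must be 'affine' or 'nonrigid'")
        self.moving = np.atleast_2d(np.asarray(moving, dtype=float))
        self.fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
        if len(self.moving) < 4 or len(self.fixed) < 4:
            raise ValueError("both point sets need at least 4 points")
        self.mode = mode
        self.params = params or CPDParams()

    def fit(self) -> CPDResult:
        p = self.params
        d = 3
        x_mm, y_mm = self.fixed, self.moving
        if p.normalize:
            both = np.vstack([x_mm, y_mm])
            mu = both.mean(axis=0)
            scale = float(np.sqrt(((both - mu) ** 2).sum(axis=1).mean()))
            scale = max(scale, 1e-12)
        else:
            mu, scale = np.zeros(3), 1.0
        x = (x_mm - mu) / scale
        y0 = (y_mm - mu) / scale
        n, k = len(x), len(y0)

        sigma2 = float(
            ((x**2).sum() * k + (y0**2).sum() * n - 2.0 * x.sum(0) @ y0.sum(0))
            / (d * n * k)
        )

        if self.mode == "nonrigid":
            g = np.exp(-cdist(y0, y0, "sqeuclidean") / (2.0 * p.beta**2))
            w = np.zeros((k, d))
        else:
            a_lin, t_vec = np.eye(3), np.zeros(3)

        ty = y0.copy()
        sigma2_hist: list[float] = []
        obj_hist: list[float] = []
        converged = False
        it = 0
        for it in range(1, p.max_iter + 1):
            # E-step
            dist2 = cdist(ty, x, "sqeuclidean")
            pmat = np.exp(-dist2 / (2.0 * sigma2))
            c = (2.0 * np.pi * sigma2) ** (d / 2.0) * p.omega / (1.0 - p.omega) * k / n
            den = pmat.sum(axis=0) + c
            den = np.maximum(den, np.finfo(float).tiny)
            obj = (
                -np.log(den).sum()
                + n * (d / 2.0) * np.log(2.0 * np.pi * sigma2)
                - n * np.log((1.0 - p.omega) / k)
            )
            if self.mode == "nonrigid":
                obj += 0.5 * p.lambda_reg * float(np.trace(w.T @ g @ w))
            pmat = pmat / den
            p1 = pmat.sum(axis=1)  # (K,)
            pt1 = pmat.sum(axis=0)  # (N,)
            np_tot = p1.sum()
            if np_tot <= 0 or not np.isfinite(np_tot):
                raise ArithmeticError(f"CPD posterior degenerated at iteration {it}")
            px = pmat @ x  # (K, 3)

            # M-step
            if self.mode == "affine":
                mu_x = (x * pt1[:, None]).sum(0) / np_tot
                mu_y = (y0 * p1[:, None]).sum(0) / np_tot
                xh, yh = x - mu_x, y0 - mu_y
                b = (pmat @ xh).T @ yh  # Xh' P' Yh
                cc = (yh * p1[:, None]).T @ yh
                a_lin = b @ np.linalg.inv(cc)
                t_vec = mu_x - a_lin @ mu_y
                ty = y0 @ a_lin.T + t_vec
                sigma2_new = (
                    float((pt1 * (xh**2).sum(1)).sum() - np.trace(b @ a_lin.T))
                    / (np_tot * d)
                )
            else:
                lhs = g * p1[:, None] + p.lambda_reg * sigma2 * np.eye(k)
                rhs = px - y0 * p1[:, None]
                w = np.linalg.solve(lhs, rhs)
                ty = y0 + g @ w
                sigma2_new = (
                    float((pt1 * (x**2).sum(1)).sum())
                    - 2.0 * float((px * ty).sum())
                    + float((p1 * (ty**2).sum(1)).sum())
                ) / (np_tot * d)

            if not np.isfinite(sigma2_new) or not np.isfinite(ty).all():
                raise ArithmeticError(f"CPD produced non-finite update at iteration {it}")
            sigma2 = float(sigma2_new)
            underflow = sigma2 < 1e-8
            sigma2 = max(sigma2, 1e-8)
            sigma2_hist.append(sigma2)
            obj_hist.append(float(obj))
            if underflow:
                converged = True
                break
            if len(obj_hist) >= 2:
                prev, cur = obj_hist[-2], obj_hist[-1]
                if abs(prev - cur) < p.tol * (abs(prev) + 1.0):
                    converged = True
                    break

        # de-normalize (joint normalization: common mu/scale cancels cleanly)
        if self.mode == "affine":
            transform = AffineTransform(a_lin, mu - a_lin @ mu + scale * t_vec)
        else:
            transform = NonrigidWarp(
                control_points=y_mm.copy(),
                kernel_width=p.beta * scale,
                weights=scale * w,
            )
        return CPDResult(
            transform=transform,
            mode=self.mode,
            sigma2_history=sigma2_hist,
            objective_history=obj_hist,
            n_iter=it,
            converged=converged,
        )


def cpd_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    mode: str = "affine",
    params: CPDParams | None = None,
) -> AffineTransform | NonrigidWarp:
    """Fit CPD and return just the transform (see :class:`CoherentPointDrift`)."""
    return CoherentPointDrift(moving, fixed, mode, params).fit().transform


# ---------------------------------------------------------------------------
# full surface-to-atlas pipeline
# ---------------------------------------------------------------------------


def register_surface_to_atlas(
    individual: TriangleMesh,
    ind_lm: LandmarkSet,
    atlas: TriangleMesh,
    atlas_lm: LandmarkSet,
    sensors: SensorSet,
    method: str = "cpd_affine",
    params: CPDParams | None = None,
    dp: DownsampleParams | None = None,
    smooth_iterations: int = 10,
    nasion_cut_offset_mm: float = 10.0,
    project: bool = True,
) -> SensorSet:
    """Map individual-space sensors onto the atlas head surface.

    ``method`` selects the mapping:

    * ``landmarks`` — least-squares affine between the five cranial landmarks;
    * ``cpd_affine`` / ``cpd_nonrigid`` — smooth the individual surface,
      box-grid downsample both surfaces (~3000 / ~9000 nodes), rigidly
      pre-align from {nasion, Cz, LPA, RPA}, cut both below the nasion
      (an axial plane ``nasion_cut_offset_mm`` under it, to keep nose-slope
      differences from biasing the fit), then CPD-register the point sets and
      push the sensors through the composed mapping.

    With ``project`` the mapped sensors are snapped to the nearest atlas node.
    """
    if method == "landmarks":
        try:
            aff = affine_from_landmarks(ind_lm, atlas_lm)
        except ValueError as exc:
            raise StageError("landmark-affine", str(exc)) from exc
        mapped = sensors.transformed(aff.apply)
    elif method in ("cpd_affine", "cpd_nonrigid"):
        mode = method.removeprefix("cpd_")
        if dp is None:
            dp = DownsampleParams(target_nodes=3000 if mode == "affine" else 9000)
        try:
            ind_smooth = (
                smooth_lowpass(individual, iterations=smooth_iterations)
                if smooth_iterations > 0
                else individual
            )
        except Exception as exc:
            raise StageError("smoothing", str(exc)) from exc
        try:
            ind_pts = downsample_grid(ind_smooth, dp).points
            atlas_pts = downsample_grid(atlas, dp).points
        except Exception as exc:
            raise StageError("downsampling", str(exc)) from exc
        try:
            rigid = rigid_from_landmarks(ind_lm, atlas_lm, RIGID_LANDMARKS)
        except ValueError as exc:
            raise StageError("rigid-prealignment", str(exc)) from exc
        try:
            frame = head_frame_from_landmarks(atlas_lm)
            level = float(frame.superior_coordinate(atlas_lm["nasion"])[0]) - nasion_cut_offset_mm
            moving = cut_points_below_plane(rigid.apply(ind_pts), frame, level)
            fixed = cut_points_below_plane(atlas_pts, frame, level)
        except Exception as exc:
            raise StageError("nasion-cut", str(exc)) from exc
        try:
            result = CoherentPointDrift(moving, fixed, mode, params).fit()
        except Exception as exc:
            raise StageError("cpd", str(exc)) from exc
        mapped = sensors.transformed(
            lambda pts: result.transform.apply(rigid.apply(pts))
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    if project:
        hits = nearest_node(atlas, mapped.positions)
        return SensorSet(
            mapped.labels,
            np.stack([atlas.vertices[i] for i, _ in hits]),
            [i for i, _ in hits],
        )
    return mapped
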