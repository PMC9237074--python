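"""Quantitative evaluation: deviation maps, localization errors, scalar-field
regions and peaks, Dice overlap, and paired method comparison.

Summary statistics are reported as median and median absolute deviation
(MAD).  Method comparisons use paired two-sided Wilcoxon signed-rank tests
with Benjamini-Hochberg FDR correction across all method pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError
from .mesh_core import LandmarkSet, SensorSet, TriangleMesh, nearest_node
from .registration import IterativeClosestPoint, affine_from_landmarks


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class ScalarField:
    """Non-negative per-vertex values bound to a mesh (identified by name)."""

    values: np.ndarray
    mesh_ref: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("field values must be finite")
        if len(self.values) and self.values.min() < 0:
            raise ValueError("field values must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"node_index": np.arange(len(self.values)), "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mesh_ref: str = "") -> "ScalarField":
        df = pd.read_csv(path).sort_values("node_index")
        values = np.zeros(int(df["node_index"].max()) + 1)
        values[df["node_index"].to_numpy(int)] = df["value"].to_numpy(float)
        return cls(values, mesh_ref)


@dataclass
class RegionMask:
    """Set of vertex indices, typically the > 80%-of-maximum region."""

    node_indices: frozenset
    threshold_frac: float = 0.8
    mesh_ref: str = ""

    def __post_init__(self):
        self.node_indices = frozenset(int(i) for i in self.node_indices)
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must lie in (0, 1)")


class ErrorTable:
    """Long-format table of (subject, sensor, method, metric, value) rows."""

    COLUMNS = ["subject_id", "sensor_label", "method", "metric_name", "value"]

    def __init__(self, df: pd.DataFrame | None = None):
        self.df = (
            df.copy() if df is not None else pd.DataFrame(columns=self.COLUMNS)
        )
        if list(self.df.columns) != self.COLUMNS:
            raise ValueError(f"ErrorTable columns must be {self.COLUMNS}")
        keys = self.df[self.COLUMNS[:4]]
        if keys.duplicated().any():
            raise ValueError("duplicate (subject, sensor, method, metric) keys")

    def add(self, subject_id, sensor_label, method, metric_name, value) -> None:
        self.df.loc[len(self.df)] = [subject_id, sensor_label, method, metric_name, value]

    def extend(self, other: "ErrorTable") -> "ErrorTable":
        frames = [df for df in (self.df, other.df) if len(df)]
        if not frames:
            return ErrorTable()
        return ErrorTable(pd.concat(frames, ignore_index=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ErrorTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def median_mad(values: np.ndarray) -> tuple[float, float]:
    """Median and median absolute deviation (raw, not normal-consistent)."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


def mesh_deviation(
    recon: TriangleMesh,
    reference: TriangleMesh,
    lm_recon: LandmarkSet,
    lm_ref: LandmarkSet,
) -> tuple[ScalarField, dict]:
    """Per-vertex deviation of a reconstructed mesh from its reference.

    The reconstruction is affinely aligned to the reference via the cranial
    landmarks, refined by rigid ICP, and each aligned vertex is scored by its
    Euclidean distance to the nearest reference vertex.  Returns the deviation
    field on ``recon`` plus a median/MAD summary.
    """
    aff = affine_from_landmarks(lm_recon, lm_ref)
    aligned = aff.apply(recon.vertices)
    icp = IterativeClosestPoint(aligned, reference).fit()
    aligned = icp.transform.apply(aligned)
    dist = np.array([d for _, d in nearest_node(reference, aligned)])
    med, mad = median_mad(dist)
    return (
        ScalarField(dist, mesh_ref="recon"),
        {"median_mm": med, "mad_mm": mad, "icp_iterations": icp.n_iter},
    )


def localization_error(estimated: SensorSet, truth: SensorSet) -> ErrorTable:
    """Per-sensor Euclidean distance (mm) between estimate and truth."""
    est_labels, tru_labels = set(estimated.labels), set(truth.labels)
    if est_labels != tru_labels:
        only_e = sorted(est_labels - tru_labels)
        only_t = sorted(tru_labels - est_labels)
        raise ValueError(
            f"label mismatch; only in estimated: {only_e}; only in truth: {only_t}"
        )
    tru = {lab: pos for lab, pos, _ in truth}
    table = ErrorTable()
    for lab, pos, _ in estimated:
        err = float(np.linalg.norm(pos - tru[lab]))
        table.add("", lab, "", "euclidean_mm", err)
    return table


def match_by_position(estimated: SensorSet, truth: SensorSet) -> SensorSet:
    """Relabel detected sensors by optimal one-to-one assignment to the truth.

    Detected markers carry color-based labels; comparing them with a layout's
    ground truth requires a correspondence, found here by minimizing total
    Euclidean distance (Hungarian assignment).  Returns the matched estimated
    sensors carrying the truth labels.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    if len(estimated) == 0 or len(truth) == 0:
        return SensorSet([], np.empty((0, 3)))
    cost = cdist(estimated.positions, truth.positions)
    rows, cols = linear_sum_assignment(cost)
    return SensorSet(
        [truth.labels[j] for j in cols],
        estimated.positions[rows],
        [estimated.node_indices[i] for i in rows],
    )


def suprathreshold_region(field: ScalarField, threshold_frac: float = 0.8) -> RegionMask:
    """Nodes with value strictly greater than ``threshold_frac`` x maximum."""
    if len(field.values) == 0:
        raise EmptyResultError("empty field")
    vmax = field.values.max()
    if vmax <= 0:
        raise EmptyResultError("field has no positive values")
    idx = np.flatnonzero(field.values > threshold_frac * vmax)
    return RegionMask(frozenset(idx.tolist()), threshold_frac, field.mesh_ref)


def field_peak(
    field: ScalarField, mesh: TriangleMesh, threshold_frac: float = 0.8
) -> np.ndarray:
    """Value-weighted centroid of the suprathreshold nodes (mm)."""
    region = suprathreshold_region(field, threshold_frac)
    idx = np.array(sorted(region.node_indices), dtype=int)
    if len(idx) == 0:
        raise EmptyResultError("suprathreshold region is empty")
    w = field.values[idx]
    return (mesh.vertices[idx] * w[:, None]).sum(axis=0) / w.sum()


def dice_region(a: RegionMask, b: RegionMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two node regions."""
    if a.mesh_ref != b.mesh_ref:
        raise ValueError("regions are defined on different meshes")
    if not a.node_indices and not b.node_indices:
        raise EmptyResultError("Dice of two empty regions is undefined")
    inter = len(a.node_indices & b.node_indices)
    return 2.0 * inter / (len(a.node_indices) + len(b.node_indices))


# ---------------------------------------------------------------------------
# paired method comparison
# ---------------------------------------------------------------------------


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank p-value and W statistic.

    Zero differences are dropped; exact null for n <= 25 non-zero pairs, else
    normal approximation with continuity correction.  All-zero differences
    give p = 1 by convention.
    """
    diff = np.asarray(x, float) - np.asarray(y, float)
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 1.0, 0.0
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    return float(res.pvalue), float(res.statistic)


def compare_methods(
    errors: ErrorTable, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise paired Wilcoxon tests across methods with BH-FDR correction.

    Observations are paired on (subject, sensor); every method must cover the
    same pairs.  Returns one row per method pair with raw p, BH-adjusted p,
    the normal-quantile z-equivalent and a significance flag at ``alpha``.
    """
    df = errors.df[errors.df["metric_name"] == metric]
    if df.empty:
        raise ValueError(f"no rows with metric {metric!r}")
    wide = df.pivot_table(
        index=["subject_id", "sensor_label"], columns="method", values="value"
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"unpaired data: method(s) {missing} lack some observations")
    methods = list(wide.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    if len(wide) < 6:
        raise ValueError("need at least 6 paired observations")
    rows = []
    for a, b in combinations(methods, 2):
        p, w = _paired_wilcoxon(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append({"method_a": a, "method_b": b, "statistic": w, "p_raw": p})
    report = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(report["p_raw"].to_numpy(), method="fdr_bh")
    report["p_fdr"] = p_adj
    report["z"] = stats.norm.isf(np.clip(report["p_raw"], 1e-300, 1.0) / 2.0)
    report["significant"] = report["p_fdr"] < alpha
    return report
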