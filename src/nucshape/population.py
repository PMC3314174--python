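"""Population-level analysis: curvature heat maps, group statistics,
metric covariance and hierarchical clustering.

The signature visualization is the curvature heat map: every nucleus
boundary is cut at its farthest-from-centroid point, straightened, and
resampled to a common length; the resulting signed-curvature columns are
placed side by side sorted by increasing MNC, so a population's blebbing
structure is visible at a glance. Group comparisons use the one-tailed
Welch (unequal-variance) t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from nucshape.contour import Contour, arc_positions, perimeter
from nucshape.metrics import CurvatureProfile, NucleusMetrics

_ID_COLUMNS = ("image_id", "nucleus_id", "group")


@dataclass
class PopulationTable:
    """Metrics rows plus aligned curvature profiles for a population.

    ``rows`` is a DataFrame with one row per nucleus (the NucleusMetrics
    columns plus a ``group`` label); ``profiles`` and ``contours`` are
    aligned lists (contours are optional and only needed for arc-length
    weighted heat-map resampling; without them, spacing is assumed uniform,
    which is exact for the constant-side-length contours the extraction
    stage outputs).
    """

    rows: pd.DataFrame
    profiles: list[CurvatureProfile]
    contours: list[Contour] | None = None

    def __post_init__(self) -> None:
        if "group" not in self.rows.columns:
            raise ValueError("rows must carry a 'group' column")
        if len(self.rows) != len(self.profiles):
            raise ValueError("metrics rows and profiles must align")
        if self.contours is not None and len(self.contours) != len(self.rows):
            raise ValueError("contours must align with rows")

    @classmethod
    def from_metrics(cls, metrics: list[NucleusMetrics],
                     profiles: list[CurvatureProfile],
                     groups: list[str] | str = "all",
                     contours: list[Contour] | None = None) -> "PopulationTable":
        df = pd.DataFrame([m.to_dict() for m in metrics])
        df["group"] = groups if not isinstance(groups, str) else groups
        return cls(df, profiles, contours)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class HeatmapMatrix:
    """Curvature heat map: rows = normalized boundary position, columns =
    nuclei in non-decreasing MNC order, values clipped to ±cutoff."""

    values: np.ndarray
    cutoff: float
    column_order: np.ndarray
    mnc: np.ndarray  # sorted MNC per column


def _resample_profile(prof: CurvatureProfile, contour: Contour | None,
                      n_rows: int) -> np.ndarray:
    kappa = prof.kappa
    n = len(kappa)
    if contour is not None:
        pos = arc_positions(contour.vertices)
        total = perimeter(contour.vertices)
    else:
        pos = np.arange(n, dtype=float)
        total = float(n)
    pos_ext = np.append(pos, total)
    k_ext = np.append(kappa, kappa[0])
    target = np.linspace(0.0, total, n_rows, endpoint=False)
    return np.interp(target, pos_ext, k_ext)


def heatmap(pop: PopulationTable, n_rows: int = 200,
            cutoff: float = 0.15) -> HeatmapMatrix:
    """Assemble the MNC-sorted curvature heat map of a population.

    Every profile must already start at the farthest-from-centroid vertex
    (see :func:`nucshape.metrics.rotate_to_start`); row 0 of the matrix is
    that boundary position. Curvature magnitudes above ``cutoff`` are set to
    the cutoff (display clipping only; the MNC ordering uses unclipped
    values).
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    mnc = pop.rows["mnc"].to_numpy(float)
    order = np.argsort(mnc, kind="stable")
    cols = []
    for i in order:
        contour = pop.contours[i] if pop.contours is not None else None
        cols.append(_resample_profile(pop.profiles[i], contour, n_rows))
    values = np.clip(np.column_stack(cols), -cutoff, cutoff)
    return HeatmapMatrix(values, cutoff, order, mnc[order])


def welch_t_one_tailed(a, b, direction: str = "less") -> tuple[float, float, float]:
    """One-tailed Welch (unequal-variance) t-test.

    ``direction='less'`` tests the alternative mean(a) < mean(b);
    ``'greater'`` the reverse. Returns (t, Welch–Satterthwaite df, p).
    Significance convention: p <= 0.05.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t-test undefined")
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class ClusteringResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    tree: dict


def _tree_to_dict(node, labels) -> dict:
    if node.is_leaf():
        return {"name": labels[node.id]}
    return {
        "height": float(node.dist),
        "children": [_tree_to_dict(node.left, labels),
                     _tree_to_dict(node.right, labels)],
    }


def metric_clustering(pop: PopulationTable, method: str = "pearson",
                      linkage_method: str = "average") -> ClusteringResult:
    """Correlation matrix and hierarchical clustering of the measure panel.

    Metric columns are correlated pairwise (Pearson by default, Spearman
    optional) over nuclei; measures are agglomeratively clustered with
    distance 1 − |r| and the requested linkage. Constant (zero-variance)
    columns are excluded with a warning.
    """
    df = pop.rows.drop(columns=[c for c in _ID_COLUMNS if c in pop.rows], errors="ignore")
    df = df.select_dtypes(include=[np.number]).dropna(axis=1, how="all")
    if len(df) < 10 or df.shape[1] < 3:
        raise ValueError("clustering needs >= 10 nuclei and >= 3 metrics")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant metric columns excluded: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    corr = df.corr(method=method)
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    tree = _tree_to_dict(hierarchy.to_tree(z), list(corr.columns))
    return ClusteringResult(corr, z, tree)


def group_summary(pop: PopulationTable, metrics: list[str] | None = None) -> pd.DataFrame:
    """Box-plot statistics per group and metric.

    Quartiles use linear interpolation; whiskers follow the 1.5·IQR rule
    (most extreme data point within 1.5·IQR of the nearer quartile).
    """
    df = pop.rows
    if metrics is None:
        metrics = [c for c in df.columns
                   if c not in _ID_COLUMNS and pd.api.types.is_numeric_dtype(df[c])]
    records = []
    for g, sub in df.groupby("group", sort=True):
        for m in metrics:
            vals = sub[m].dropna().to_numpy(float)
            if len(vals) == 0:
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            in_lo = vals[vals >= q1 - 1.5 * iqr]
            in_hi = vals[vals <= q3 + 1.5 * iqr]
            records.append({
                "group": g, "metric": m, "n": len(vals),
                "mean": vals.mean(), "median": med, "q1": q1, "q3": q3,
                "whisker_low": in_lo.min() if len(in_lo) else q1,
                "whisker_high": in_hi.max() if len(in_hi) else q3,
            })
    return pd.DataFrame(records)
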