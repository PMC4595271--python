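"""Developmental profile analysis: scaling, clustering and trend classes.

Expression or concentration matrices (rows = genes or compounds, columns
= condition cells ordered by developmental stage) are row-standardized
(z-scores, the R ``scale`` convention with an n-1 SD), clustered
hierarchically (Euclidean distance, complete linkage by default, the R
``hclust``/``heatmap`` defaults) with the dendrogram exportable as
Newick, and clustered by K-means to find shared developmental trends.

Per-row developmental trends over the ordered stages are classified into
``increased`` / ``decreased`` / ``stable`` by the Pearson correlation of
the profile with the stage ranks (|r| >= 0.7 by default), with ``NC``
(not clustered) for rows detected at too few stages and ``ND`` for rows
absent from the reference annotation.  A ``peaked`` subtype flags
profiles whose interior maximum exceeds both endpoint values at least
2-fold.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

TREND_R_THRESHOLD = 0.7
PEAK_FOLD = 2.0


def row_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores: subtract the row mean, divide by the n-1 row SD.

    Constant rows map to all zeros with a ``UserWarning``; every row must
    have at least 2 finite values.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("row scaling needs at least 2 columns")
    if np.isfinite(values).sum(axis=1).min() < 2:
        bad = matrix.index[np.isfinite(values).sum(axis=1) < 2]
        raise ValueError(f"rows with <2 finite values: {list(bad)}")
    means = np.nanmean(values, axis=1, keepdims=True)
    sds = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    constant = (sds == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) scaled to all zeros",
            UserWarning,
            stacklevel=2,
        )
    sds[sds == 0] = 1.0
    return pd.DataFrame(
        (values - means) / sds, index=matrix.index, columns=matrix.columns
    )


@dataclass
class DendrogramResult:
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def hierarchical_cluster(
    matrix: pd.DataFrame,
    *,
    metric: str = "euclidean",
    method: str = "complete",
) -> DendrogramResult:
    """Agglomerative clustering of rows with Newick dendrogram export.

    Ties between equal-distance merges are broken deterministically by
    scipy's ordering (lowest-index pair first).  Newick branch lengths
    are differences of merge heights, so leaf depth equals the root merge
    height.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values after scaling")
    link = hierarchy.linkage(values, method=method, metric=metric)
    leaves = hierarchy.leaves_list(link)
    labels = [str(lab) for lab in matrix.index]
    return DendrogramResult(
        linkage=link,
        leaf_order=[labels[i] for i in leaves],
        newick=_linkage_to_newick(link, labels),
    )


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)
    out = io.StringIO()

    def walk(node, parent_height: float) -> None:
        length = parent_height - node.dist
        if node.is_leaf():
            out.write(f"{labels[node.id]}:{length:.10g}")
        else:
            out.write("(")
            walk(node.left, node.dist)
            out.write(",")
            walk(node.right, node.dist)
            out.write(f"):{length:.10g}")

    out.write("(")
    walk(tree.left, tree.dist)
    out.write(",")
    walk(tree.right, tree.dist)
    out.write(");")
    return out.getvalue()


@dataclass
class KMeansTrendResult:
    labels: pd.Series
    centroids: pd.DataFrame
    upward_clusters: list[int]
    upward_members: list[str] = field(default_factory=list)
    inertia: float = float("nan")


def kmeans_trends(
    matrix: pd.DataFrame,
    k: int,
    seed: int,
    *,
    stage_index: Sequence[float] | None = None,
    r_upward: float = TREND_R_THRESHOLD,
) -> KMeansTrendResult:
    """K-means clustering of (scaled) profiles with upward-cluster selection.

    A cluster is called upward when the Pearson correlation of its
    centroid with the stage index (column order by default) is at least
    ``r_upward``; the returned member set is the union of upward
    clusters.  k-means++ initialization with a fixed seed makes the run
    reproducible.
    """
    n = len(matrix)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    x = stage_index if stage_index is not None else np.arange(matrix.shape[1])
    x = np.asarray(x, dtype=float)
    if x.shape[0] != matrix.shape[1]:
        raise ValueError("stage_index length must match column count")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.columns)
    upward = []
    for c in range(k):
        centroid = centroids.iloc[c].to_numpy()
        if np.std(centroid) == 0 or np.std(x) == 0:
            continue
        if stats.pearsonr(centroid, x).statistic >= r_upward:
            upward.append(c)
    members = [str(row) for row, lab in zip(matrix.index, labels) if lab in upward]
    return KMeansTrendResult(
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        centroids=centroids,
        upward_clusters=upward,
        upward_members=members,
        inertia=float(km.inertia_),
    )


@dataclass(frozen=True)
class TrendClass:
    row_id: str
    trend: str  # increased | decreased | stable | NC | ND
    r_stage: float
    peaked: bool


def classify_trend(
    profile: Sequence[float],
    detected: Sequence[bool] | None = None,
    *,
    row_id: str = "",
    in_reference: bool = True,
    r_threshold: float = TREND_R_THRESHOLD,
    peak_fold: float = PEAK_FOLD,
    min_detected: int = 3,
) -> TrendClass:
    """Classify a per-stage profile into a developmental trend class.

    ``ND`` when the row is absent from the reference annotation; ``NC``
    when detected at fewer than ``min_detected`` stages; otherwise the
    Pearson correlation r of the detected values with their stage ranks
    decides: increased (r >= threshold), decreased (r <= -threshold) or
    stable.  ``peaked`` flags an interior maximum at least ``peak_fold``
    times both endpoint values.
    """
    values = np.asarray(profile, dtype=float)
    if detected is None:
        mask = np.isfinite(values) & (values > 0)
    else:
        mask = np.asarray(detected, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("detection mask must match profile length")
    if not in_reference:
        return TrendClass(row_id, "ND", float("nan"), False)
    if mask.sum() < min_detected:
        return TrendClass(row_id, "NC", float("nan"), False)

    ranks = np.arange(1, len(values) + 1, dtype=float)
    v, x = values[mask], ranks[mask]
    if np.std(v) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(v, x).statistic)
    if r >= r_threshold:
        trend = "increased"
    elif r <= -r_threshold:
        trend = "decreased"
    else:
        trend = "stable"

    peaked = False
    imax = int(np.argmax(values[mask]))
    if 0 < imax < mask.sum() - 1:
        peak = v[imax]
        peaked = bool(peak >= peak_fold * v[0] and peak >= peak_fold * v[-1])
    return TrendClass(row_id, trend, r, peaked)


def classify_trends(
    stage_means: pd.DataFrame,
    detected: pd.DataFrame | None = None,
    *,
    reference_ids: Sequence[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """classify_trend applied row-wise to a rows x stages matrix."""
    ref = set(reference_ids) if reference_ids is not None else None
    rows = []
    for row_id in stage_means.index:
        tc = classify_trend(
            stage_means.loc[row_id].to_numpy(),
            detected.loc[row_id].to_numpy() if detected is not None else None,
            row_id=str(row_id),
            in_reference=(ref is None or row_id in ref),
            **kwargs,
        )
        rows.append(
            {
                "row_id": tc.row_id,
                "trend": tc.trend,
                "r_stage": tc.r_stage,
                "peaked": tc.peaked,
            }
        )
    return pd.DataFrame(rows)


def heatmap(
    scaled: pd.DataFrame, path=None, *, method: str = "complete"
):  # pragma: no cover - plotting convenience
    """Basic clustered heatmap (red-blue) of a row-scaled matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchical_cluster(scaled, method=method).leaf_order
    data = scaled.loc[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * scaled.shape[1]), max(4, 0.2 * len(scaled)))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(order)), order, fontsize=6)
    ax.set_xticks(range(scaled.shape[1]), [str(c) for c in scaled.columns],
                  rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
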