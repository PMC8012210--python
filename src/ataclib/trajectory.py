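"""Supervised trajectories through ordered clusters in LSI space.

Given a user-supplied cluster order (e.g. a known differentiation
hierarchy), the trajectory is the piecewise-linear path through the
successive cluster mean coordinates, interpolated to 100 points; each
cell's pseudotime is the index of its nearest path point rescaled to
[0, 100].  Per-cluster outliers (beyond a distance quantile from their
own cluster mean) are excluded.  Pseudotime-binned, smoothed feature
matrices support correlating regulatory dynamics (e.g. peak accessibility
vs gene expression) along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

N_PATH_POINTS = 100


@dataclass
class Trajectory:
    ordered_clusters: list
    path: np.ndarray  # N_PATH_POINTS x dims
    pseudotime: np.ndarray  # per cell, NaN outside trajectory/outliers
    outlier_quantile: float


def _interpolate_path(means: np.ndarray, n_points: int = N_PATH_POINTS) -> np.ndarray:
    """Piecewise-linear path through cluster means, arc-length uniform."""
    seg = np.diff(means, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    if total == 0:
        return np.repeat(means[:1], n_points, axis=0)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    targets = np.linspace(0, total, n_points)
    out = np.empty((n_points, means.shape[1]))
    for i, t in enumerate(targets):
        j = min(np.searchsorted(cum, t, side="right") - 1, len(seg) - 1)
        frac = (t - cum[j]) / seg_len[j] if seg_len[j] > 0 else 0.0
        out[i] = means[j] + frac * seg[j]
    return out


def fit_trajectory(
    embedding: np.ndarray,
    labels: np.ndarray,
    ordered_clusters: list,
    outlier_quantile: float = 0.9,
    spline_smooth: bool = False,
) -> Trajectory:
    """Align cells to a path through the ordered cluster means.

    Cells outside the listed clusters, or farther from their own cluster
    mean than that cluster's ``outlier_quantile`` distance, get pseudotime
    NaN.  With ``spline_smooth`` a univariate smoothing spline of each
    coordinate against the initial pseudotime refines the path once and
    cells re-align to the spline.
    """
    labels = np.asarray(labels)
    for c in ordered_clusters:
        if not (labels == c).any():
            raise ValueError(f"cluster {c!r} in the order has no cells")
    means = np.vstack([embedding[labels == c].mean(axis=0) for c in ordered_clusters])
    pseudotime = np.full(len(labels), np.nan)
    in_traj = np.isin(labels, ordered_clusters)
    keep = in_traj.copy()
    for i, c in enumerate(ordered_clusters):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(embedding[members] - means[i], axis=1)
        cutoff = np.quantile(d, outlier_quantile)
        keep[members[d > cutoff]] = False
    path = _interpolate_path(means)
    cells = np.flatnonzero(keep)
    d2 = ((embedding[cells, None, :] - path[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    pseudotime[cells] = nearest / (N_PATH_POINTS - 1) * 100.0
    if spline_smooth and len(cells) > 10:
        from scipy.interpolate import UnivariateSpline

        t0 = pseudotime[cells]
        order = np.argsort(t0, kind="stable")
        # strictly increasing abscissa for the spline fit
        t_sorted = t0[order] + np.arange(len(order)) * 1e-9
        new_path = np.empty_like(path)
        grid = np.linspace(t_sorted.min(), t_sorted.max(), N_PATH_POINTS)
        for dim in range(embedding.shape[1]):
            spl = UnivariateSpline(t_sorted, embedding[cells][order, dim], k=3)
            new_path[:, dim] = spl(grid)
        d2 = ((embedding[cells, None, :] - new_path[None, :, :]) ** 2).sum(axis=2)
        pseudotime[cells] = d2.argmin(axis=1) / (N_PATH_POINTS - 1) * 100.0
        path = new_path
    return Trajectory(list(ordered_clusters), path, pseudotime, outlier_quantile)


def pseudotime_binned_matrix(
    X,
    trajectory: Trajectory,
    n_bins: int = 100,
    smooth_window: int = 11,
    target_depth: float = 1e4,
) -> np.ndarray:
    """bins x features matrix of smoothed, depth-normalised log1p means.

    Cells fall into equal-width pseudotime bins over [0, 100]; empty bins
    are linearly interpolated; a centred moving average of width
    ``smooth_window`` smooths each feature across bins.  More than 50%
    empty bins raises.
    """
    from .features import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        X = X.counts
    X = sp.csr_matrix(X, dtype=float)
    t = trajectory.pseudotime
    cells = np.flatnonzero(~np.isnan(t))
    bins = np.minimum((t[cells] / 100.0 * n_bins).astype(int), n_bins - 1)
    depth = np.asarray(X[cells].sum(axis=1)).ravel()
    depth[depth == 0] = 1.0
    out = np.zeros((n_bins, X.shape[1]))
    occupied = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        members = cells[bins == b]
        if len(members) == 0:
            continue
        occupied[b] = True
        sub = X[members]
        d = np.asarray(sub.sum(axis=1)).ravel()
        d[d == 0] = 1.0
        norm = sp.diags(target_depth / d) @ sub
        out[b] = np.log1p(np.asarray(norm.mean(axis=0)).ravel())
    if occupied.sum() < n_bins / 2:
        raise ValueError("more than 50% of pseudotime bins are empty; trajectory too sparse")
    # linear interpolation of empty bins
    idx = np.arange(n_bins)
    for j in range(out.shape[1]):
        out[~occupied, j] = np.interp(idx[~occupied], idx[occupied], out[occupied, j])
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(out, ((pad, pad), (0, 0)), mode="edge")
        out = np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, padded)
    return out


def correlate_along_trajectory(
    binned_a: np.ndarray,
    binned_b: np.ndarray,
    pairs: list[tuple[int, int]],
    r_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Pearson r over pseudotime bins for candidate (row-of-A, row-of-B)
    column pairs; constant profiles are excluded; BH-FDR across tested
    pairs and ``is_link`` where r > cutoff."""
    from scipy import stats

    n_bins = binned_a.shape[0]
    rows = []
    for a_idx, b_idx in pairs:
        a = binned_a[:, a_idx]
        b = binned_b[:, b_idx]
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        t = r * np.sqrt(n_bins - 2) / np.sqrt(max(1 - r**2, 1e-12))
        p = 2 * stats.t.sf(abs(t), df=n_bins - 2)
        rows.append({"a": a_idx, "b": b_idx, "r": r, "p_value": p})
    if not rows:
        return pd.DataFrame(columns=["a", "b", "r", "p_value", "fdr", "is_link"])
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_link"] = out["r"] > r_cutoff
    return out
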