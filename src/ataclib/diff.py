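"""Bias-matched background selection and Wilcoxon marker features.

Accessibility differences between cell groups are confounded by data
quality: cells with more fragments or higher TSS enrichment look "more
accessible" everywhere.  Marker testing therefore compares each group
against a background of cells matched on (log10 fragment count, TSS
enrichment), selected by nearest-neighbour matching in quantile-scaled
bias space, and uses the Wilcoxon rank-sum test per feature with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _quantile_scale(values: np.ndarray) -> np.ndarray:
    """Map values to their quantile rank in [0, 1]."""
    ranks = stats.rankdata(values, method="average")
    return (ranks - 1) / max(len(values) - 1, 1)


def match_background_cells(
    group: list[int] | np.ndarray,
    pool: list[int] | np.ndarray,
    bias: np.ndarray,
    ratio: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Select bias-matched background cells from ``pool``.

    ``bias`` has one row per cell (indexed by the integer ids used in
    ``group`` / ``pool``) and one column per bias feature, typically
    (log10 n_frags, tss_enrichment).  Features are quantile-scaled to
    [0, 1] over group ∪ pool; each group cell takes its nearest pool cell
    in that space, without replacement while the pool lasts.  Returns
    ``round(ratio * len(group))`` pool indices.
    """
    group = np.asarray(group)
    pool = np.asarray(pool)
    if len(np.intersect1d(group, pool)):
        raise ValueError("pool must be disjoint from group")
    del seed  # matching is deterministic; kept for interface stability
    both = np.concatenate([group, pool])
    scaled = np.column_stack([_quantile_scale(bias[both, j]) for j in range(bias.shape[1])])
    g_scaled = scaled[: len(group)]
    p_scaled = scaled[len(group):]
    n_needed = int(round(ratio * len(group)))
    reps = -(-n_needed // len(group))
    queries = np.vstack([g_scaled] * reps)[:n_needed]
    chosen: list[int] = []
    available = np.ones(len(pool), dtype=bool)
    if n_needed > len(pool):
        warnings.warn("pool smaller than required background; sampling with replacement")
    nn = NearestNeighbors(n_neighbors=min(len(pool), 25)).fit(p_scaled)
    _, neighbor_idx = nn.kneighbors(queries)
    for row in neighbor_idx:
        pick = None
        for j in row:
            if available[j]:
                pick = j
                break
        if pick is None:  # all near neighbours taken: reuse the closest
            pick = row[0]
        else:
            available[pick] = False
        chosen.append(pool[pick])
    return np.asarray(chosen)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration over assignments.

    Valid for small samples (n1 + n2 <= ~20); handles ties by enumerating
    the permutation distribution of the rank sum on the observed ranks.
    """
    from itertools import combinations

    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    observed = ranks[:n1].sum()
    total = 0
    as_extreme = 0
    mean_sum = ranks.sum() * n1 / len(combined)
    obs_dev = abs(observed - mean_sum)
    for combo in combinations(range(len(combined)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean_sum) >= obs_dev - 1e-9:
            as_extreme += 1
    return as_extreme / total


def wilcoxon_vectorized(
    X: np.ndarray, n_group: int, exact_max_n: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum per column of ``X``.

    The first ``n_group`` rows are the group, the rest background.  Uses
    the tie-corrected normal approximation, or exact enumeration when the
    total sample size is small.  Constant columns get p = 1.  Returns
    (p-values, rank-biserial-like effect direction via mean rank diff).
    """
    n_total, n_feat = X.shape[0], X.shape[1]
    n_bg = n_total - n_group
    ranks = stats.rankdata(X, axis=0)
    R1 = ranks[:n_group].sum(axis=0)
    U1 = R1 - n_group * (n_group + 1) / 2
    mu = n_group * n_bg / 2
    # tie correction per feature
    tie_term = np.zeros(n_feat)
    for j in range(n_feat):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    sigma2 = n_group * n_bg / 12 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    constant = sigma2 <= 0
    sigma = np.sqrt(np.where(constant, 1.0, sigma2))
    z = (U1 - mu) / sigma
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(constant, 1.0, np.minimum(p, 1.0))
    if n_total <= exact_max_n:
        for j in range(n_feat):
            if constant[j]:
                continue
            p[j] = _exact_ranksum_pvalue(X[:n_group, j], X[n_group:, j])
    effect = U1 / (n_group * n_bg) - 0.5
    return p, effect


def wilcoxon_markers(
    matrix,
    group: np.ndarray,
    background: np.ndarray,
    fdr_cutoff: float = 0.01,
    log2fc_cutoff: float = 1.0,
    feature_names: list[str] | None = None,
    normalize_depth: bool = True,
) -> pd.DataFrame:
    """Marker features for ``group`` vs ``background`` cell indices.

    log2 fold change uses pseudocount 1 on depth-normalised (to 10k) group
    means.  Markers satisfy fdr <= fdr_cutoff and log2fc >= log2fc_cutoff.
    """
    from .features import FeatureMatrix

    if isinstance(matrix, FeatureMatrix):
        if feature_names is None:
            feature_names = matrix.features.names
        X = matrix.counts
    else:
        X = sp.csr_matrix(matrix)
    if len(group) == 0 or len(background) == 0:
        raise ValueError("group and background must be non-empty")
    rows = np.concatenate([group, background])
    sub = np.asarray(X[rows].todense(), dtype=float)
    if normalize_depth:
        depth = sub.sum(axis=1, keepdims=True)
        depth[depth == 0] = 1.0
        sub = sub / depth * 1e4
    n_group = len(group)
    p, _effect = wilcoxon_vectorized(sub, n_group)
    mean_in = sub[:n_group].mean(axis=0)
    mean_bg = sub[n_group:].mean(axis=0)
    lfc = np.log2((mean_in + 1) / (mean_bg + 1))
    all_zero = (mean_in == 0) & (mean_bg == 0)
    lfc = np.where(all_zero, 0.0, lfc)
    p = np.where(all_zero, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature": feature_names if feature_names is not None else np.arange(sub.shape[1]),
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "mean_in_group": mean_in,
            "mean_in_background": mean_bg,
        }
    )
    out["is_marker"] = (out["fdr"] <= fdr_cutoff) & (out["log2_fold_change"] >= log2fc_cutoff)
    return out


def markers_per_cluster(
    matrix,
    labels: np.ndarray,
    bias: np.ndarray,
    fdr_cutoff: float = 0.01,
    log2fc_cutoff: float = 1.0,
    ratio: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Each cluster vs bias-matched cells from all other clusters."""
    labels = np.asarray(labels)
    results = []
    for lab in np.unique(labels):
        group = np.flatnonzero(labels == lab)
        pool = np.flatnonzero(labels != lab)
        bg = match_background_cells(group, pool, bias, ratio=ratio, seed=seed)
        res = wilcoxon_markers(matrix, group, bg, fdr_cutoff, log2fc_cutoff)
        res.insert(1, "group", lab)
        results.append(res)
    return pd.concat(results, ignore_index=True)
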