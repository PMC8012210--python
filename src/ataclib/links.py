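"""Co-accessibility and peak-to-gene linkage over low-overlap cell aggregates.

Single-cell accessibility is near-binary, so pairwise correlations are
computed on KNN cell aggregates: groups of k mutually similar cells in
LSI space, retained only while their pairwise membership overlap stays
below a cap.  Aggregate profiles (depth-normalised, log1p) feed Pearson
correlations between intra-chromosomal peak pairs (co-accessibility) or
between peaks and matched gene expression within a distance window
(peak-to-gene links), with BH-FDR across tested pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def knn_aggregates(
    embedding: np.ndarray,
    k: int = 100,
    max_overlap: float = 0.8,
    n_groups: int = 500,
    seed: int = 0,
) -> list[np.ndarray]:
    """Low-overlap KNN cell groups.

    Seed cells are sampled in random order; each group is the k nearest
    neighbours (inclusive) of its seed, and a group sharing more than
    ``max_overlap * k`` members with any retained group is dropped.
    """
    n = embedding.shape[0]
    if n < k:
        raise ValueError("need at least k cells")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    order = rng.permutation(n)[: min(n, max(n_groups * 5, n_groups))]
    kept: list[np.ndarray] = []
    kept_sets: list[set] = []
    cap = max_overlap * k
    for seed_cell in order:
        members = idx[seed_cell]
        mset = set(members.tolist())
        if any(len(mset & s) > cap for s in kept_sets):
            continue
        kept.append(np.sort(members))
        kept_sets.append(mset)
        if len(kept) >= n_groups:
            break
    if len(kept) < 2 and k < n:
        raise ValueError("could not form >= 2 aggregates under the overlap cap")
    return kept


def aggregate_profiles(X, groups: list[np.ndarray], target_depth: float = 1e4) -> np.ndarray:
    """Aggregates x features: log1p of depth-normalised summed counts."""
    from .features import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        X = X.counts
    X = sp.csr_matrix(X)
    rows = []
    for g in groups:
        s = np.asarray(X[g].sum(axis=0)).ravel()
        tot = s.sum()
        rows.append(np.log1p(s / tot * target_depth if tot > 0 else s))
    return np.vstack(rows)


def _pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding columns of A and B."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = (A * B).sum(axis=0)
    den = np.sqrt((A**2).sum(axis=0) * (B**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def coaccessibility(
    peak_matrix,
    peaks: pd.DataFrame | None,
    groups: list[np.ndarray],
    max_dist: int = 250_000,
    r_cutoff: float = 0.45,
) -> pd.DataFrame:
    """Correlated intra-chromosomal peak pairs within ``max_dist``.

    Distance is midpoint-to-midpoint.  Constant peaks are excluded with a
    log message.  Returns peak index pairs with distance and r >= cutoff.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 aggregates")
    if peaks is None:
        peaks = peak_matrix.features.intervals
    P = aggregate_profiles(peak_matrix, groups)
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()
    const = P.std(axis=0) == 0
    if const.any():
        logger.info("%d constant peaks excluded from co-accessibility", int(const.sum()))
    ia, ib = [], []
    for chrom in pd.unique(chroms):
        pos_idx = np.flatnonzero((chroms == chrom) & ~const)
        order = pos_idx[np.argsort(mid[pos_idx], kind="stable")]
        m = mid[order]
        for i in range(len(order)):
            j = np.searchsorted(m, m[i] + max_dist, side="right")
            for jj in range(i + 1, j):
                ia.append(order[i])
                ib.append(order[jj])
    if not ia:
        return pd.DataFrame(columns=["peak_a", "peak_b", "distance", "r"])
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    r = _pearson_columns(P[:, ia], P[:, ib])
    dist = np.abs(mid[ia] - mid[ib])
    out = pd.DataFrame({"peak_a": ia, "peak_b": ib, "distance": dist, "r": r})
    return out[out["r"] >= r_cutoff].reset_index(drop=True)


def peak2gene(
    peak_matrix,
    peaks: pd.DataFrame | None,
    expression,
    genes: pd.DataFrame,
    groups: list[np.ndarray],
    max_dist: int = 250_000,
    r_cutoff: float = 0.45,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Peak-gene pairs whose accessibility and expression correlate.

    ``genes`` needs chrom/name and a TSS (strand-aware from start/end, or
    a ``tss`` column); peaks with midpoint within ``max_dist`` of the TSS
    are tested.  Returns every tested pair with r, p and BH-FDR plus a
    ``is_link`` flag (r >= r_cutoff and fdr <= fdr_cutoff).
    """
    from scipy import stats

    if peaks is None:
        peaks = peak_matrix.features.intervals
    P = aggregate_profiles(peak_matrix, groups)
    E = aggregate_profiles(expression, groups)
    expr_names = (
        expression.features.names if hasattr(expression, "features") else list(genes["name"])
    )
    expr_idx = {g: i for i, g in enumerate(expr_names)}
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()
    if "tss" in genes.columns:
        tss = genes["tss"].to_numpy()
    else:
        plus = genes.get("strand", pd.Series("+", index=genes.index)).to_numpy() != "-"
        tss = np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)
    rows = []
    n_agg = len(groups)
    for gi, grow in enumerate(genes.itertuples(index=False)):
        if grow.name not in expr_idx:
            logger.info("gene %s absent from expression matrix; skipped", grow.name)
            continue
        e = E[:, expr_idx[grow.name]]
        if e.std() == 0:
            continue
        near = np.flatnonzero((chroms == grow.chrom) & (np.abs(mid - tss[gi]) <= max_dist))
        for pi in near:
            a = P[:, pi]
            if a.std() == 0:
                continue
            r = float(np.corrcoef(a, e)[0, 1])
            t = r * np.sqrt(max(n_agg - 2, 1)) / np.sqrt(max(1 - r**2, 1e-12))
            p = 2 * stats.t.sf(abs(t), df=max(n_agg - 2, 1))
            rows.append(
                {
                    "peak": int(pi),
                    "gene": grow.name,
                    "distance": int(abs(mid[pi] - tss[gi])),
                    "r": r,
                    "p_value": p,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["peak", "gene", "distance", "r", "p_value", "fdr", "is_link"])
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_link"] = (out["r"] >= r_cutoff) & (out["fdr"] <= fdr_cutoff)
    return out


def links_to_bedpe(links: pd.DataFrame, peaks: pd.DataFrame, genes: pd.DataFrame, path: str) -> None:
    """BEDPE export of peak-to-gene links (peak interval vs gene TSS)."""
    gmap = genes.set_index("name")
    with open(path, "w") as fh:
        for row in links.itertuples(index=False):
            p = peaks.iloc[int(row.peak)]
            g = gmap.loc[row.gene]
            tss = g["start"] if g.get("strand", "+") != "-" else g["end"] - 1
            fh.write(
                f"{p['chrom']}\t{p['start']}\t{p['end']}\t{g['chrom']}\t{tss}\t{tss + 1}"
                f"\t{row.gene}\t{row.r:.4f}\n"
            )
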