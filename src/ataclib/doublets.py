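"""Heterotypic doublet detection by synthetic-doublet projection.

Doublets — two nuclei sharing a barcode — superimpose two cells' signal
and show up between or across clusters.  The detector synthesises
in-silico doublets by summing random pairs of observed cells, projects
them into the fitted LSI subspace (no refit; the projection is linear),
and scores every real cell by how enriched synthetic doublets are among
its nearest neighbours in that space.  Real doublets sit where synthetic
ones land; singlets do not.

The scorer is an sklearn-style estimator: ``fit`` takes the counts used
for the LSI model plus the fitted model, ``fit_predict``-style access via
``scores_`` and ``filter_doublets``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .lsi import IterativeLSI, _as_csr


def synthesize_doublets(
    X, n_synthetic: int, seed: int = 0
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Element-wise sums of uniformly sampled distinct cell pairs.

    Returns (synthetic counts, parent index pairs of shape (n, 2)).
    """
    X = _as_csr(X)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to synthesise doublets")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_synthetic)
    b = rng.integers(0, n - 1, size=n_synthetic)
    b = np.where(b >= a, b + 1, b)  # distinct partner, uniform over pairs
    parents = np.column_stack([a, b])
    synth = X[a] + X[b]
    return synth.tocsr(), parents


def doublet_scores(
    real_embedding: np.ndarray,
    synthetic_embedding: np.ndarray,
    k: int = 10,
) -> pd.DataFrame:
    """Synthetic-neighbour enrichment per real cell.

    Both embeddings must live in the same retained-component space.  For
    each real cell, x = number of synthetic points among its k nearest
    neighbours in the pooled (real + synthetic) set, excluding itself;
    expected = k * nSyn / (nSyn + nReal - 1); enrichment = x / expected;
    score = -log10 upper-tail binomial P(X >= x | k, p).
    """
    n_real = real_embedding.shape[0]
    n_syn = synthetic_embedding.shape[0]
    pooled = np.vstack([real_embedding, synthetic_embedding])
    if k >= pooled.shape[0]:
        raise ValueError("k must be smaller than the pooled embedding size")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pooled)
    _, idx = nn.kneighbors(real_embedding)
    # each real cell is in the pool: drop its own index (which may not be
    # first under ties), then keep its first k true neighbours
    not_self = idx != np.arange(n_real)[:, None]
    take = not_self & (np.cumsum(not_self, axis=1) <= k)
    x = ((idx >= n_real) & take).sum(axis=1)
    p = n_syn / (n_syn + n_real - 1)
    expected = k * p
    enrichment = x / expected
    # P(X >= x) = sf(x - 1)
    pvals = stats.binom.sf(x - 1, k, p)
    score = -np.log10(np.maximum(pvals, 1e-300))
    out = pd.DataFrame(
        {"n_synthetic_neighbors": x, "enrichment": enrichment, "score": score}
    )
    out["rank"] = (
        out[["enrichment", "score"]]
        .apply(tuple, axis=1)
        .rank(method="first", ascending=False)
        .astype(int)
    )
    return out


def n_cells_to_remove(n_cells: int, filter_ratio: float = 1.0) -> int:
    """Expected doublet load scales with cell loading: ~1% per 1,000
    cells, i.e. round(filter_ratio * n^2 / 100,000)."""
    return int(round(filter_ratio * n_cells**2 / 100_000))


def filter_doublets(
    scores: pd.DataFrame,
    filter_ratio: float = 1.0,
    n_frags: np.ndarray | None = None,
    barcodes: list[str] | None = None,
) -> np.ndarray:
    """Indices of cells removed as putative doublets.

    The top ``n_remove`` cells by enrichment are removed; ties break by
    higher score, then higher fragment count, then barcode.
    """
    if filter_ratio < 0:
        raise ValueError("filter_ratio must be >= 0")
    n = len(scores)
    n_remove = n_cells_to_remove(n, filter_ratio)
    if n_remove >= n:
        raise ValueError(f"would remove all {n} cells; lower filter_ratio")
    if n_remove == 0:
        return np.array([], dtype=int)
    order = pd.DataFrame(
        {
            "enrichment": scores["enrichment"].to_numpy(),
            "score": scores["score"].to_numpy(),
            "n_frags": n_frags if n_frags is not None else np.zeros(n),
            "barcode": barcodes if barcodes is not None else [str(i) for i in range(n)],
        }
    )
    ranked = order.sort_values(
        ["enrichment", "score", "n_frags", "barcode"],
        ascending=[False, False, False, True],
        kind="stable",
    )
    return ranked.index.to_numpy()[:n_remove]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with averaged ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class SyntheticDoubletDetector(BaseEstimator):
    """End-to-end doublet scoring against a fitted LSI model.

    Parameters
    ----------
    k : neighbourhood size in the pooled embedding.
    n_synthetic : number of synthetic doublets (default: one per cell).
    filter_ratio : scales the number of cells removed
        (``round(ratio * n^2 / 1e5)``).
    random_state : seed for pair sampling.

    Attributes
    ----------
    scores_ : DataFrame with enrichment / score / rank per real cell.
    removed_ : integer indices of cells flagged for removal.
    parents_ : synthetic parent pairs.
    """

    def __init__(
        self,
        k: int = 10,
        n_synthetic: int | None = None,
        filter_ratio: float = 1.0,
        random_state: int = 0,
    ):
        self.k = k
        self.n_synthetic = n_synthetic
        self.filter_ratio = filter_ratio
        self.random_state = random_state

    def fit(self, X, lsi_model: IterativeLSI, n_frags: np.ndarray | None = None):
        X = _as_csr(X)
        n = X.shape[0]
        n_syn = self.n_synthetic if self.n_synthetic is not None else n
        synth, parents = synthesize_doublets(X, n_syn, seed=self.random_state)
        real_emb = lsi_model.embedding_
        syn_emb = lsi_model.transform(synth)
        self.scores_ = doublet_scores(real_emb, syn_emb, k=self.k)
        self.parents_ = parents
        self.removed_ = filter_doublets(
            self.scores_, self.filter_ratio, n_frags=n_frags
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        """Boolean mask: True = flagged doublet."""
        mask = np.zeros(len(self.scores_), dtype=bool)
        mask[self.removed_] = True
        return mask
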