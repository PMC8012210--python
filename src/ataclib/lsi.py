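"""Latent semantic indexing for single-cell chromatin accessibility.

The reduction backbone: term-frequency/inverse-document-frequency
normalisation of the (binary-ish, very sparse) cells x features counts,
truncated SVD, removal of components correlated with sequencing depth,
and — because a single pass on raw tiles mostly captures depth — an
iterative scheme that reselects the most cluster-variable features from a
preliminary clustering and refits.  The SVD subspace is linear, so
held-out cells (or bulk profiles, or synthetic doublets) are embedded by
projection through the stored IDF weights and loadings without refitting.

Estimators follow scikit-learn conventions (``fit`` / ``transform``,
fitted attributes with trailing underscores) and compose with sklearn
pipelines.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

TFIDF_SCALE = 10_000.0


def _as_csr(X) -> sp.csr_matrix:
    from .features import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        X = X.counts
    return sp.csr_matrix(X, dtype=np.float64)


class TfIdfTransformer(BaseEstimator, TransformerMixin):
    """log(1 + tf * idf * 10,000) normalisation.

    tf is each cell's count divided by its total over the selected
    features; idf is n_cells / number of cells in which the feature is
    non-zero, learned at fit time and reused for held-out cells.
    """

    def __init__(self, scale: float = TFIDF_SCALE):
        self.scale = scale

    def fit(self, X, y=None) -> "TfIdfTransformer":
        X = _as_csr(X)
        occurrence = np.asarray((X > 0).sum(axis=0)).ravel()
        if (occurrence == 0).any():
            raise ValueError("all-zero feature in selected set; reselect features")
        self.idf_ = X.shape[0] / occurrence
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, barcodes=None) -> sp.csr_matrix:
        X = _as_csr(X)
        depth = np.asarray(X.sum(axis=1)).ravel()
        if (depth == 0).any():
            zeros = np.flatnonzero(depth == 0)
            names = [barcodes[i] for i in zeros] if barcodes is not None else list(zeros)
            raise ValueError(f"cells with zero counts on selected features: {names[:10]}")
        tf = sp.diags(1.0 / depth) @ X
        out = tf @ sp.diags(self.idf_ * self.scale)
        out.data = np.log1p(out.data)
        return out.tocsr()


def tfidf(X, scale: float = TFIDF_SCALE):
    """One-shot TF-IDF; returns (normalised matrix, idf vector)."""
    t = TfIdfTransformer(scale=scale).fit(X)
    return t.transform(X), t.idf_


class LSI(BaseEstimator, TransformerMixin):
    """Truncated SVD of the TF-IDF matrix with depth decorrelation.

    Parameters
    ----------
    n_components : SVD rank (must be < min(matrix dims)).
    depth_corr_cutoff : components whose embedding coordinates have
        absolute Pearson correlation with log10 cell depth above this are
        dropped from ``retained_components_``.
    random_state : seeds the Lanczos start vector; fixed seed gives a
        reproducible decomposition.

    Attributes
    ----------
    idf_, loadings_ (features x components), singular_values_,
    embedding_ (training cells x components), retained_components_.
    """

    def __init__(
        self,
        n_components: int = 30,
        depth_corr_cutoff: float = 0.75,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.depth_corr_cutoff = depth_corr_cutoff
        self.random_state = random_state

    def fit(self, X, y=None, depth: np.ndarray | None = None) -> "LSI":
        X = _as_csr(X)
        if depth is None:
            depth = np.asarray(X.sum(axis=1)).ravel()
        k = self.n_components
        if k >= min(X.shape):
            k = min(X.shape) - 1
            warnings.warn(f"rank-deficient input; reducing n_components to {k}")
        self.tfidf_ = TfIdfTransformer().fit(X)
        self.idf_ = self.tfidf_.idf_
        Xn = self.tfidf_.transform(X)
        rng = np.random.default_rng(self.random_state)
        v0 = rng.standard_normal(min(Xn.shape))
        u, s, vt = svds(Xn, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
        # deterministic sign: largest-magnitude loading positive
        signs = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
        signs[signs == 0] = 1.0
        vt = vt * signs[:, None]
        u = u * signs[None, :]
        self.loadings_ = vt.T
        self.singular_values_ = s
        self.embedding_ = np.asarray(Xn @ self.loadings_)
        logd = np.log10(np.maximum(depth, 1))
        if np.std(logd) == 0:
            corr = np.zeros(len(s))
        else:
            e = self.embedding_
            es = e.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = ((e - e.mean(0)) * (logd - logd.mean())[:, None]).mean(0) / (es * logd.std())
            corr = np.nan_to_num(corr)
        self.depth_correlation_ = corr
        self.retained_components_ = np.flatnonzero(np.abs(corr) <= self.depth_corr_cutoff)
        if len(self.retained_components_) == 0:
            warnings.warn("all components depth-correlated; retaining all")
            self.retained_components_ = np.arange(len(s))
        return self

    def transform(self, X) -> np.ndarray:
        """Project cells through stored idf and loadings (all components)."""
        X = _as_csr(X)
        if X.shape[1] != self.tfidf_.n_features_in_:
            raise ValueError("feature dimension mismatch with fitted model")
        Xn = self.tfidf_.transform(X)
        return np.asarray(Xn @ self.loadings_)

    def embedding(self, X=None) -> np.ndarray:
        """Coordinates restricted to the depth-decorrelated components."""
        coords = self.embedding_ if X is None else self.transform(X)
        return coords[:, self.retained_components_]


def lsi_fit(X, n_components: int = 30, seed: int = 0, depth=None) -> LSI:
    return LSI(n_components=n_components, random_state=seed).fit(X, depth=depth)


def lsi_project(model: LSI, X) -> np.ndarray:
    """Embed new profiles in the fitted subspace (retained components)."""
    return model.transform(X)[:, model.retained_components_]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def snn_graph(embedding: np.ndarray, k_neighbors: int = 30):
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")
    adj = adj + sp.eye(n, format="csr")
    shared = adj @ adj.T
    shared = sp.triu(shared, k=1).tocoo()
    union = 2 * (k + 1) - shared.data
    weights = shared.data / union
    keep = weights > 1.0 / 15.0  # prune weak SNN edges (Seurat-style cutoff)
    return shared.row[keep], shared.col[keep], weights[keep], n


def cluster_cells(
    embedding: np.ndarray,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """SNN graph + Leiden modularity communities; deterministic per seed."""
    import igraph
    import leidenalg

    rows, cols, weights, n = snn_graph(embedding, k_neighbors)
    g = igraph.Graph(n=n, edges=list(zip(rows.tolist(), cols.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(weights),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------
# iterative LSI
# ---------------------------------------------------------------------------

class IterativeLSI(BaseEstimator, TransformerMixin):
    """LSI with variable-feature reselection over multiple rounds.

    Round 1 runs LSI on the ``n_top_features`` most accessible features
    and clusters the result; per-cluster pseudo-bulk log2 counts-per-
    million profiles then give a per-feature across-cluster variance, the
    top ``n_var_features`` of which seed the next round.  The final
    round's model and embedding are kept.

    Attributes: ``model_`` (the final :class:`LSI`), ``feature_indices_``
    (columns used by the final round), ``embedding_`` (retained
    components), ``prelim_labels_``.
    """

    def __init__(
        self,
        n_iterations: int = 2,
        n_components: int = 30,
        n_top_features: int = 25_000,
        n_var_features: int = 25_000,
        cluster_resolution: float = 0.8,
        k_neighbors: int = 30,
        random_state: int = 0,
    ):
        self.n_iterations = n_iterations
        self.n_components = n_components
        self.n_top_features = n_top_features
        self.n_var_features = n_var_features
        self.cluster_resolution = cluster_resolution
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit(self, X, y=None) -> "IterativeLSI":
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        X = _as_csr(X)
        depth = np.asarray(X.sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=0)).ravel()
        nz = np.flatnonzero(totals > 0)
        top = nz[np.argsort(totals[nz], kind="stable")[::-1][: self.n_top_features]]
        features = np.sort(top)
        labels = None
        for it in range(self.n_iterations):
            model = LSI(
                n_components=self.n_components, random_state=self.random_state
            ).fit(X[:, features], depth=depth)
            emb = model.embedding()
            if it == self.n_iterations - 1:
                break
            labels = cluster_cells(
                emb,
                k_neighbors=self.k_neighbors,
                resolution=self.cluster_resolution,
                seed=self.random_state,
            )
            if len(np.unique(labels)) < 2:
                warnings.warn(
                    "fewer than 2 preliminary clusters; keeping top-accessible features"
                )
                continue
            features = self._variable_features(X, labels)
        self.model_ = model
        self.feature_indices_ = features
        self.embedding_ = emb
        self.prelim_labels_ = labels
        return self

    def _variable_features(self, X: sp.csr_matrix, labels: np.ndarray) -> np.ndarray:
        profiles = []
        for lab in np.unique(labels):
            rows = np.flatnonzero(labels == lab)
            s = np.asarray(X[rows].sum(axis=0)).ravel()
            cpm = s / max(s.sum(), 1) * 1e6
            profiles.append(np.log2(cpm + 1))
        P = np.vstack(profiles)
        var = P.var(axis=0)
        top = np.argsort(var, kind="stable")[::-1][: self.n_var_features]
        top = top[var[top] > 0]
        return np.sort(top)

    def transform(self, X) -> np.ndarray:
        X = _as_csr(X)
        return lsi_project(self.model_, X[:, self.feature_indices_])


def iterative_lsi(X, **kwargs) -> IterativeLSI:
    return IterativeLSI(**kwargs).fit(X)


def estimated_lsi(
    X,
    n_landmarks: int,
    seed: int = 0,
    **iterative_kwargs,
) -> tuple[np.ndarray, IterativeLSI, np.ndarray]:
    """Fit iterative LSI on a landmark subset; project the rest.

    Returns (embedding for all cells in input order, fitted model,
    landmark indices).  With ``n_landmarks == n_cells`` this is exactly
    :func:`iterative_lsi` on the full matrix.
    """
    X = _as_csr(X)
    n = X.shape[0]
    n_components = iterative_kwargs.get("n_components", 30)
    if n_landmarks < 2 * n_components:
        raise ValueError("n_landmarks must be at least 2 * n_components")
    if n_landmarks > n:
        raise ValueError("n_landmarks exceeds number of cells")
    rng = np.random.default_rng(seed)
    if n_landmarks == n:
        landmarks = np.arange(n)
    else:
        landmarks = np.sort(rng.choice(n, size=n_landmarks, replace=False))
    fitted = IterativeLSI(random_state=seed, **iterative_kwargs).fit(X[landmarks])
    emb = np.empty((n, fitted.embedding_.shape[1]))
    emb[landmarks] = fitted.embedding_
    rest = np.setdiff1d(np.arange(n), landmarks)
    if len(rest):
        emb[rest] = fitted.transform(X[rest])
    return emb, fitted, landmarks
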