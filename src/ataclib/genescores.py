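"""Gene activity scores from chromatin accessibility.

A gene score summarises accessibility in and around a gene as a proxy for
its expression.  The default model ("model42") integrates signal across
the whole gene body, extends the body 5 kb upstream of the TSS, applies
bi-directional exponential distance decay beyond the extended body out to
100 kb, truncates each gene's window at its neighbours' extended bodies,
and scales scores by inverse gene size.  Weights act on the genome tile
matrix, so scores are a sparse weighted sum of tile counts followed by
per-cell depth normalisation.

A model family is expressed through :class:`GeneScoreModelSpec` (region
basis, decay shape, boundary handling), with named presets covering the
main model classes so alternatives can be benchmarked against matched
expression with :func:`evaluate_gene_models`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .features import FeatureMatrix, FeatureSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneScoreModelSpec:
    """Parameters of one gene-score model.

    use_gene_body : include the whole gene body (else promoter/TSS only).
    upstream_body_extension : bases added upstream of the TSS, same weight
        as the body (default 5000).
    decay : "exponential", "linear" or "none" — weight shape outside the
        (extended) body.
    decay_constant : e-folding distance in bases for exponential decay.
    weight_floor : additive constant on the decayed weight (default e^-1),
        keeping distal tiles from vanishing entirely.
    max_extension : how far beyond each end of the extended body tiles may
        contribute (0 disables distal signal).
    respect_gene_boundaries : truncate the window at the nearest
        neighbouring extended gene body.
    gene_size_scaling : linearly map inverse gene length into
        [1, scale_max]; small genes get up-weighted.
    target_depth : per-cell total the score matrix is normalised to
        (0 disables depth normalisation).
    """

    use_gene_body: bool = True
    upstream_body_extension: int = 5000
    decay: str = "exponential"
    decay_constant: float = 5000.0
    weight_floor: float = float(np.exp(-1))
    max_extension: int = 100_000
    respect_gene_boundaries: bool = True
    gene_size_scaling: bool = True
    scale_max: float = 5.0
    target_depth: float = 10_000.0
    promoter_window: int = 2500  # half-width of TSS window when body unused

    def __post_init__(self) -> None:
        if self.decay_constant <= 0:
            raise ValueError("decay_constant must be > 0")
        if self.max_extension < 0 or self.scale_max < 1:
            raise ValueError("max_extension >= 0 and scale_max >= 1 required")
        if self.decay not in {"exponential", "linear", "none"}:
            raise ValueError("decay must be exponential|linear|none")


MODEL42 = GeneScoreModelSpec()

#: Named presets spanning the main model classes (region basis x decay x
#: boundary handling); "model42" is the default used downstream.
MODEL_PRESETS: dict[str, GeneScoreModelSpec] = {
    "model42": MODEL42,
    "body_decay_noboundary": replace(MODEL42, respect_gene_boundaries=False),
    "body_linear_decay": replace(MODEL42, decay="linear"),
    "body_only": replace(MODEL42, decay="none", max_extension=0),
    "promoter_decay": replace(
        MODEL42, use_gene_body=False, upstream_body_extension=0
    ),
    "promoter_only": replace(
        MODEL42, use_gene_body=False, upstream_body_extension=0, decay="none", max_extension=0
    ),
}


def gene_score_weight(distance: np.ndarray | float, spec: GeneScoreModelSpec) -> np.ndarray:
    """Weight at a signed distance (bases) from the extended gene body.

    distance = 0 anywhere inside the body (extended upstream); beyond
    ``max_extension`` the weight is exactly 0.  For exponential decay the
    weight is exp(-|d| / decay_constant) + weight_floor, hence 1 + e^-1 at
    d = 0 under the defaults.
    """
    d = np.abs(np.asarray(distance, dtype=float))
    if spec.decay == "exponential":
        w = np.exp(-d / spec.decay_constant) + spec.weight_floor
    elif spec.decay == "linear":
        w = np.maximum(1.0 - d / max(spec.max_extension, 1), 0.0) + spec.weight_floor
    else:
        w = np.where(d == 0, 1.0, 0.0)
    w = np.where(d > spec.max_extension, 0.0, w)
    return w


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Gene annotation from BED6-like TSV: chrom, start, end, name, score, strand."""
    df = pd.read_csv(path, sep="\t", header=None)
    return pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "name": df[3].astype(str),
            "strand": df[5].astype(str) if df.shape[1] >= 6 else "+",
        }
    )


def _extended_bodies(genes: pd.DataFrame, spec: GeneScoreModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (ext_start, ext_end): region treated as distance 0."""
    start = genes["start"].to_numpy(np.int64)
    end = genes["end"].to_numpy(np.int64)
    plus = genes["strand"].to_numpy() != "-"
    tss = np.where(plus, start, end - 1)
    if spec.use_gene_body:
        ext_start = np.where(plus, start - spec.upstream_body_extension, start)
        ext_end = np.where(plus, end, end + spec.upstream_body_extension)
    else:
        ext_start = np.where(plus, tss - spec.upstream_body_extension - spec.promoter_window,
                             tss - spec.promoter_window)
        ext_end = np.where(plus, tss + spec.promoter_window + 1,
                           tss + spec.promoter_window + spec.upstream_body_extension + 1)
    return ext_start, ext_end


def gene_windows(
    genes: pd.DataFrame,
    chrom_sizes,
    spec: GeneScoreModelSpec = MODEL42,
    tile_size: int = 500,
) -> pd.DataFrame:
    """Per-gene weighted tile footprint.

    Returns a long table (gene, chrom, tile, weight).  Each gene's window
    is its extended body padded by ``max_extension`` on both sides, clipped
    to the chromosome and, when boundaries are respected, truncated at the
    nearest neighbouring extended body (exclusive).  Tile weights come
    from :func:`gene_score_weight` at the tile-center distance, which
    makes weights tie-free.
    """
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("zero- or negative-length genes not allowed")
    genes = genes.reset_index(drop=True)
    ext_start, ext_end = _extended_bodies(genes, spec)
    rows = []
    for chrom, idx in genes.groupby("chrom").groups.items():
        if chrom not in chrom_sizes:
            logger.info("gene(s) on %s skipped: chromosome not in sizes", chrom)
            continue
        clen = chrom_sizes[chrom]
        idx = np.asarray(list(idx))
        order = idx[np.argsort(ext_start[idx], kind="stable")]
        es, ee = ext_start[order], ext_end[order]
        for j, gi in enumerate(order):
            lo = es[j] - spec.max_extension
            hi = ee[j] + spec.max_extension
            if spec.respect_gene_boundaries:
                others = np.arange(len(order)) != j
                left_edges = ee[others & (ee <= es[j])]
                if len(left_edges):
                    lo = max(lo, int(left_edges.max()))
                right_edges = es[others & (es >= ee[j])]
                if len(right_edges):
                    hi = min(hi, int(right_edges.min()))
            lo = max(int(lo), 0)
            hi = min(int(hi), clen)
            if hi <= lo:
                continue
            if ee[j] > clen or es[j] < 0:
                logger.info("gene %s window truncated at chromosome bounds", genes.at[gi, "name"])
            t0 = lo // tile_size
            t1 = -(-hi // tile_size)
            tiles = np.arange(t0, t1)
            centers = tiles * tile_size + tile_size / 2
            dist = np.where(
                centers < es[j], es[j] - centers, np.where(centers >= ee[j], centers - ee[j] + 1, 0.0)
            )
            w = gene_score_weight(dist, spec)
            keep = w > 0
            if not keep.any():
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "gene": genes.at[gi, "name"],
                        "chrom": chrom,
                        "tile": tiles[keep],
                        "weight": w[keep],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["gene", "chrom", "tile", "weight"])
    return pd.concat(rows, ignore_index=True)


def _gene_size_scale(genes: pd.DataFrame, spec: GeneScoreModelSpec) -> pd.Series:
    if not spec.gene_size_scaling:
        return pd.Series(1.0, index=genes["name"])
    inv = 1.0 / (genes["end"] - genes["start"]).to_numpy(float)
    lo, hi = inv.min(), inv.max()
    if hi == lo:
        scaled = np.ones_like(inv)
    else:
        scaled = 1.0 + (spec.scale_max - 1.0) * (inv - lo) / (hi - lo)
    return pd.Series(scaled, index=genes["name"])


def build_gene_score_matrix(
    tile_matrix: FeatureMatrix,
    genes: pd.DataFrame,
    chrom_sizes,
    spec: GeneScoreModelSpec = MODEL42,
    tile_size: int = 500,
) -> FeatureMatrix:
    """Cells x genes score matrix from the tile matrix.

    score(cell, gene) = size_scale(gene) * sum_tiles weight * count,
    followed by per-cell normalisation to ``spec.target_depth`` total.
    A tile inside two gene windows contributes to both genes.
    """
    windows = gene_windows(genes, chrom_sizes, spec, tile_size)
    tiles = tile_matrix.features.intervals
    # global tile index = chrom offset + local tile
    offsets = {}
    off = 0
    for chrom in chrom_sizes.names:
        offsets[chrom] = off
        off += -(-chrom_sizes[chrom] // tile_size)
    if off != len(tiles):
        raise ValueError("tile matrix tiling does not match chrom sizes / tile_size")
    gene_names = list(genes["name"])
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    if len(windows):
        col = windows["chrom"].map(offsets).to_numpy() + windows["tile"].to_numpy()
        row = windows["gene"].map(gene_idx).to_numpy()
        W = sp.coo_matrix(
            (windows["weight"].to_numpy(), (col, row)), shape=(len(tiles), len(gene_names))
        ).tocsr()
    else:
        W = sp.csr_matrix((len(tiles), len(gene_names)))
    raw = (tile_matrix.counts @ W).tocsr()
    scale = _gene_size_scale(genes, spec).to_numpy()
    raw = raw @ sp.diags(scale)
    if spec.target_depth > 0:
        depth = np.asarray(raw.sum(axis=1)).ravel()
        norm = np.divide(spec.target_depth, depth, out=np.zeros_like(depth), where=depth > 0)
        scores = sp.diags(norm) @ raw
    else:
        scores = raw
    feats = FeatureSet(
        genes[["chrom", "start", "end", "name"]].reset_index(drop=True), kind="gene"
    )
    return FeatureMatrix(list(tile_matrix.barcodes), feats, scores.tocsr())


# ---------------------------------------------------------------------------
# model evaluation against matched expression
# ---------------------------------------------------------------------------

def _aggregate(matrix: FeatureMatrix, groups: pd.Series) -> pd.DataFrame:
    """Mean profile per cell group; rows = groups, cols = feature names."""
    groups = groups.reindex(matrix.barcodes)
    out = {}
    X = matrix.counts
    for g in sorted(groups.dropna().unique()):
        rows = np.flatnonzero((groups == g).to_numpy())
        out[g] = np.asarray(X[rows].mean(axis=0)).ravel()
    return pd.DataFrame(out, index=matrix.features.names).T


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def select_gene_sets(
    expr_agg: pd.DataFrame, n_differential: int = 1000, n_variable: int = 2000
) -> dict[str, list[str]]:
    """Top differentially expressed (largest across-group spread relative
    to within noise — here range/mean on aggregates) and top variable
    genes from aggregated expression."""
    mean = expr_agg.mean(axis=0)
    spread = expr_agg.max(axis=0) - expr_agg.min(axis=0)
    diff_stat = spread / (mean + 1e-9)
    var_stat = expr_agg.var(axis=0)
    n_genes = expr_agg.shape[1]
    if n_differential > n_genes or n_variable > n_genes:
        logger.info("fewer genes (%d) than requested; using all available", n_genes)
    diff = diff_stat.sort_values(ascending=False).index[: min(n_differential, n_genes)]
    var = var_stat.sort_values(ascending=False).index[: min(n_variable, n_genes)]
    return {"differential": list(diff), "variable": list(var)}


def evaluate_gene_models(
    models: dict[str, FeatureMatrix],
    expression: FeatureMatrix,
    groups: pd.Series,
    n_differential: int = 1000,
    n_variable: int = 2000,
) -> pd.DataFrame:
    """Benchmark gene-score models against matched expression.

    Four tests: {per-gene Pearson across cell aggregates, per-aggregate
    Pearson across genes} x {differential gene set, variable gene set}.
    Returns one row per model with the mean correlation in each test, the
    overall mean, and the rank (1 = best overall).
    """
    expr_agg = _aggregate(expression, groups)
    gene_sets = select_gene_sets(expr_agg, n_differential, n_variable)
    records = []
    for name, scores in models.items():
        score_agg = _aggregate(scores, groups)
        common = [g for g in expr_agg.columns if g in score_agg.columns]
        row: dict[str, float | str] = {"model": name}
        for set_name, genes_in_set in gene_sets.items():
            gs = [g for g in genes_in_set if g in common]
            e = expr_agg[gs].to_numpy()
            s = score_agg[gs].to_numpy()
            per_gene = [_safe_corr(e[:, j], s[:, j]) for j in range(len(gs))]
            per_aggregate = [_safe_corr(e[i], s[i]) for i in range(e.shape[0])]
            row[f"r_gene_{set_name}"] = float(np.nanmean(per_gene))
            row[f"r_aggregate_{set_name}"] = float(np.nanmean(per_aggregate))
        test_cols = [k for k in row if k.startswith("r_")]
        row["mean_r"] = float(np.mean([row[k] for k in test_cols]))
        records.append(row)
    table = pd.DataFrame(records).set_index("model")
    table["rank"] = table["mean_r"].rank(ascending=False).astype(int)
    return table.sort_values("rank")
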