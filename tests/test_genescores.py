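"""Gene score weights, windows, matrix assembly, model benchmarking."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ataclib.features import FeatureMatrix, FeatureSet, tile_features
from ataclib.fragments import ChromSizes
from ataclib.genescores import (
    MODEL42,
    MODEL_PRESETS,
    GeneScoreModelSpec,
    build_gene_score_matrix,
    evaluate_gene_models,
    gene_score_weight,
    gene_windows,
)

E1 = float(np.exp(-1))


def test_weight_closed_form_values():
    assert gene_score_weight(0, MODEL42) == pytest.approx(1 + E1)
    assert gene_score_weight(5000, MODEL42) == pytest.approx(2 * E1)
    assert gene_score_weight(100_001, MODEL42) == 0.0
    assert gene_score_weight(100_000, MODEL42) > 0.0


def test_weight_symmetric_and_non_increasing():
    d = np.linspace(0, 100_000, 500)
    w_pos = gene_score_weight(d, MODEL42)
    w_neg = gene_score_weight(-d, MODEL42)
    np.testing.assert_allclose(w_pos, w_neg)
    assert (np.diff(w_pos) <= 1e-12).all()


def test_isolated_gene_window_clipped_to_chromosome():
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [50_000], "end": [60_000], "name": ["g"], "strand": ["+"]}
    )
    sizes = ChromSizes({"chr1": 120_000})
    win = gene_windows(genes, sizes, MODEL42, tile_size=500)
    # extended body [45k, 60k); window would be [-55k, 160k) -> [0, 120k)
    assert win["tile"].min() == 0
    assert win["tile"].max() == 120_000 // 500 - 1
    # weight 1+e^-1 inside the extended body
    inside = win[(win["tile"] >= 45_000 // 500) & (win["tile"] < 60_000 // 500)]
    np.testing.assert_allclose(inside["weight"], 1 + E1)


def test_neighbor_boundary_truncation_two_gene_toy():
    """Two plus-strand genes 20 kb apart: each window stops at the other's
    extended body edge."""
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [100_000, 130_000],
            "end": [110_000, 140_000],
            "name": ["a", "b"],
            "strand": ["+", "+"],
        }
    )
    sizes = ChromSizes({"chr1": 1_000_000})
    win = gene_windows(genes, sizes, MODEL42, tile_size=500)
    a = win[win["gene"] == "a"]
    b = win[win["gene"] == "b"]
    # b extended body starts at 125,000 (130k - 5k upstream): a's window
    # must not reach it; tile centers >= 125,000 belong to b only
    assert a["tile"].max() * 500 + 250 <= 125_000
    # a's extended body ends at 110,000: b's window starts there
    assert b["tile"].min() * 500 + 250 >= 110_000


def test_minus_strand_upstream_extension_side():
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [50_000], "end": [60_000], "name": ["g"], "strand": ["-"]}
    )
    spec = GeneScoreModelSpec(max_extension=0)  # body only
    sizes = ChromSizes({"chr1": 200_000})
    win = gene_windows(genes, sizes, spec, tile_size=500)
    centers = win["tile"] * 500 + 250
    # upstream of a minus-strand gene is beyond `end`: body extends to 65k
    assert centers.max() > 60_000
    assert centers.min() >= 49_500


def test_gene_score_matrix_matches_dense_oracle():
    """3 genes, 100 tiles, random counts: sparse path equals the dense
    weighted product computed independently."""
    rng = np.random.default_rng(5)
    sizes = ChromSizes({"chr1": 50_000})  # 100 tiles of 500
    genes = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [5_000, 20_000, 35_000],
            "end": [8_000, 26_000, 39_000],
            "name": ["g1", "g2", "g3"],
            "strand": ["+", "-", "+"],
        }
    )
    counts = sp.csr_matrix(rng.poisson(1.0, size=(20, 100)).astype(float))
    tiles = tile_features(sizes, 500)
    tm = FeatureMatrix([f"c{i}" for i in range(20)], tiles, counts)
    gm = build_gene_score_matrix(tm, genes, sizes, MODEL42, 500)

    win = gene_windows(genes, sizes, MODEL42, 500)
    W = np.zeros((100, 3))
    for row in win.itertuples(index=False):
        W[row.tile, ["g1", "g2", "g3"].index(row.gene)] = row.weight
    raw = counts.toarray() @ W
    length = (genes["end"] - genes["start"]).to_numpy(float)
    inv = 1 / length
    scale = 1 + 4 * (inv - inv.min()) / (inv.max() - inv.min())
    raw = raw * scale
    depth = raw.sum(axis=1, keepdims=True)
    expected = np.divide(raw * MODEL42.target_depth, depth, out=np.zeros_like(raw), where=depth > 0)
    np.testing.assert_allclose(gm.counts.toarray(), expected, rtol=1e-10)


def test_gene_scores_monotone_in_body_counts():
    sizes = ChromSizes({"chr1": 50_000})
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [20_000], "end": [25_000], "name": ["g"], "strand": ["+"]}
    )
    tiles = tile_features(sizes, 500)
    body_tile = 21_000 // 500
    base = np.zeros((1, 100))
    base[0, 10] = 5  # distal signal fixed
    spec = GeneScoreModelSpec(target_depth=0.0, gene_size_scaling=False)
    prev = -1.0
    for c in (0, 1, 5, 20):
        X = base.copy()
        X[0, body_tile] = c
        tm = FeatureMatrix(["c0"], tiles, sp.csr_matrix(X))
        gm = build_gene_score_matrix(tm, genes, sizes, spec, 500)
        score = gm.counts.toarray()[0, 0]
        assert score > prev
        prev = score


def test_all_zero_cell_gives_zero_row(dataset):
    sizes = dataset.chrom_sizes
    tm = dataset.tiles
    X = tm.counts.copy().tolil()
    X[0] = 0
    tm2 = FeatureMatrix(tm.barcodes, tm.features, sp.csr_matrix(X))
    gm = build_gene_score_matrix(tm2, dataset.sim.genes, sizes, MODEL42, 500)
    assert gm.counts[0].nnz == 0


def test_identity_and_sign_flip_evaluation():
    rng = np.random.default_rng(0)
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(10) * 1000,
            "end": np.arange(10) * 1000 + 500,
            "name": [f"g{i}" for i in range(10)],
        }
    )
    feats = FeatureSet(genes, kind="gene")
    barcodes = [f"c{i}" for i in range(30)]
    expr = rng.poisson(np.repeat(rng.uniform(1, 20, size=(3, 10)), 10, axis=0))
    em = FeatureMatrix(barcodes, feats, sp.csr_matrix(expr.astype(float)))
    groups = pd.Series(np.repeat([0, 1, 2], 10), index=barcodes)
    tab = evaluate_gene_models({"same": em}, em, groups, n_differential=5, n_variable=5)
    assert tab.loc["same", "mean_r"] == pytest.approx(1.0)
    flipped = FeatureMatrix(barcodes, feats, sp.csr_matrix(expr.max() - expr.astype(float)))
    tab2 = evaluate_gene_models({"flip": flipped}, em, groups, n_differential=5, n_variable=5)
    assert tab2.loc["flip", "mean_r"] < 0


def test_body_decay_model_outranks_promoter_only(dataset):
    """Planted gene-body accessibility drives expression: the gene-body +
    exponential-decay model must rank above promoter-only."""
    from ataclib.simulate import simulate_paired_expression

    sim = dataset.sim
    expr = simulate_paired_expression(sim, coupling=1.0, seed=7).subset_cells(
        dataset.tiles.barcodes
    )
    models = {
        name: build_gene_score_matrix(dataset.tiles, sim.genes, dataset.chrom_sizes, spec)
        for name, spec in MODEL_PRESETS.items()
        if name in ("model42", "promoter_only")
    }
    groups = pd.Series(dataset.truth["cell_type"].to_numpy(), index=dataset.tiles.barcodes)
    tab = evaluate_gene_models(models, expr, groups, n_differential=15, n_variable=30)
    assert tab.loc["model42", "rank"] < tab.loc["promoter_only", "rank"]
    assert tab.loc["model42", "r_gene_differential"] > tab.loc["promoter_only", "r_gene_differential"]
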