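"""KNN aggregates, co-accessibility, peak-to-gene links."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ataclib.features import FeatureMatrix, FeatureSet
from ataclib.links import aggregate_profiles, coaccessibility, knn_aggregates, peak2gene


def test_aggregates_whole_dataset_single_group(rng):
    emb = rng.normal(size=(50, 4))
    groups = knn_aggregates(emb, k=50, n_groups=10, seed=0)
    assert len(groups) == 1
    assert len(groups[0]) == 50


def test_aggregates_overlap_cap_enforced(rng):
    emb = rng.normal(size=(400, 5))
    groups = knn_aggregates(emb, k=40, max_overlap=0.8, n_groups=60, seed=1)
    assert len(groups) >= 2
    cap = 0.8 * 40
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            shared = len(set(groups[i]) & set(groups[j]))
            assert shared <= cap


def test_aggregates_error_when_too_few(rng):
    emb = rng.normal(size=(30, 3))
    with pytest.raises(ValueError, match="k cells"):
        knn_aggregates(emb, k=50)


def make_peak_matrix(counts, starts, chrom="chr1"):
    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": np.asarray(starts) + 501,
            "name": [f"p{i}" for i in range(len(starts))],
        }
    )
    return FeatureMatrix(
        [f"c{i}" for i in range(counts.shape[0])],
        FeatureSet(peaks, kind="peak"),
        sp.csr_matrix(counts.astype(float)),
    )


def test_duplicated_peak_perfect_coaccessibility(rng):
    base = rng.poisson(3.0, size=(120, 1)).astype(float)
    counts = np.hstack([base, base, rng.poisson(3.0, size=(120, 1))])
    pm = make_peak_matrix(counts, [0, 5_000, 10_000])
    groups = [np.arange(i * 20, (i + 1) * 20) for i in range(6)]
    out = coaccessibility(pm, None, groups, r_cutoff=0.99)
    pairs = set(zip(out["peak_a"], out["peak_b"]))
    assert (0, 1) in pairs


def test_independent_peaks_null_correlation(rng):
    counts = rng.poisson(5.0, size=(600, 50)).astype(float)
    pm = make_peak_matrix(counts, np.arange(50) * 2_000)
    groups = [np.arange(i * 30, (i + 1) * 30) for i in range(20)]
    out = coaccessibility(pm, None, groups, r_cutoff=-1.1)
    assert abs(out["r"].mean()) < 0.1
    assert len(out) == 50 * 49 // 2  # all within max_dist on one chromosome


def test_distance_gate_limits_tested_pairs(rng):
    counts = rng.poisson(5.0, size=(100, 3)).astype(float)
    pm = make_peak_matrix(counts, [0, 100_000, 300_000])
    groups = [np.arange(i * 10, (i + 1) * 10) for i in range(10)]
    out = coaccessibility(pm, None, groups, max_dist=250_000, r_cutoff=-1.1)
    pairs = set(zip(out["peak_a"], out["peak_b"]))
    assert (0, 1) in pairs and (1, 2) in pairs
    assert (0, 2) not in pairs  # 300 kb apart
    # symmetry: r(A,B) recovered regardless of order convention
    more = coaccessibility(pm, None, groups, max_dist=500_000, r_cutoff=-1.1)
    assert len(more) >= len(out)


def test_constant_peak_excluded(rng):
    counts = rng.poisson(5.0, size=(60, 2)).astype(float)
    counts[:, 1] = 0.0  # all-zero -> constant aggregate profile
    pm = make_peak_matrix(counts, [0, 1_000])
    groups = [np.arange(i * 10, (i + 1) * 10) for i in range(6)]
    out = coaccessibility(pm, None, groups, r_cutoff=-1.1)
    assert len(out) == 0  # constant aggregate profile excluded


def gene_frame(names, chrom="chr1", tss=None):
    tss = tss if tss is not None else np.arange(len(names)) * 10_000
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": tss,
            "end": np.asarray(tss) + 2_000,
            "name": names,
            "strand": "+",
        }
    )


def test_promoter_proportional_expression_r_one(rng):
    """Expression identical to promoter-peak accessibility links at r = 1."""
    counts = rng.poisson(4.0, size=(100, 2)).astype(float)
    pm = make_peak_matrix(counts, [500, 20_000])
    genes = gene_frame(["g0", "g1"], tss=[600, 20_100])
    expr = FeatureMatrix(
        pm.barcodes,
        FeatureSet(genes[["chrom", "start", "end", "name"]], kind="gene"),
        sp.csr_matrix(counts.copy()),
    )
    groups = [np.arange(i * 10, (i + 1) * 10) for i in range(10)]
    out = peak2gene(pm, None, expr, genes, groups)
    row = out[(out["peak"] == 0) & (out["gene"] == "g0")].iloc[0]
    assert row["r"] == pytest.approx(1.0)
    assert row["is_link"]


def test_peak_beyond_max_dist_not_tested(rng):
    counts = rng.poisson(4.0, size=(60, 2)).astype(float)
    pm = make_peak_matrix(counts, [300_000, 320_000])
    genes = gene_frame(["g0", "g1"], tss=[0, 310_000])
    expr = FeatureMatrix(
        pm.barcodes,
        FeatureSet(genes[["chrom", "start", "end", "name"]], kind="gene"),
        sp.csr_matrix(counts.copy()),
    )
    groups = [np.arange(i * 10, (i + 1) * 10) for i in range(6)]
    out = peak2gene(pm, None, expr, genes, groups, max_dist=250_000)
    assert "g0" not in set(out["gene"])  # both peaks > 250 kb from g0's TSS
    assert "g1" in set(out["gene"])


def test_planted_enhancer_gene_links_recovered(dataset, lsi_model):
    from ataclib.features import build_peak_matrix
    from ataclib.simulate import simulate_paired_expression

    ds = dataset
    expr = simulate_paired_expression(ds.sim, coupling=1.0, seed=7).subset_cells(
        ds.tiles.barcodes
    )
    pm = build_peak_matrix(
        ds.store,
        ds.sim.peaks[["chrom", "start", "end"]].assign(
            name=[f"p{i}" for i in range(len(ds.sim.peaks))]
        ),
    ).subset_cells(ds.tiles.barcodes)
    groups = knn_aggregates(lsi_model.embedding_, k=30, n_groups=120, seed=7)
    links = peak2gene(pm, None, expr, ds.sim.genes, groups, r_cutoff=0.45)
    pt = pm.features.intervals
    key = {(r.chrom, r.start): i for i, r in enumerate(pt.itertuples(index=False))}
    planted = ds.sim.peaks[ds.sim.peaks["role"] == "enhancer"]
    hits = 0
    for r in planted.itertuples(index=False):
        pi = key[(r.chrom, r.start)]
        sub = links[(links["peak"] == pi) & (links["gene"] == r.gene) & links["is_link"]]
        hits += len(sub) > 0
    assert hits / len(planted) >= 0.8


def test_aggregate_profiles_depth_normalised(rng):
    X = rng.poisson(5.0, size=(40, 6)).astype(float)
    groups = [np.arange(20), np.arange(20, 40)]
    P = aggregate_profiles(X, groups, target_depth=1e4)
    P2 = aggregate_profiles(X * 9, groups, target_depth=1e4)
    np.testing.assert_allclose(P, P2)
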