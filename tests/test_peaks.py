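"""Pseudo-bulk plans, coverage, summit calling, iterative overlap merge."""

import numpy as np
import pandas as pd
import pytest

from ataclib.peaks import (
    call_summits_naive,
    call_peaks_from_plan,
    export_group_coverage,
    iterative_overlap_merge,
    make_pseudobulk_plan,
    profile_to_bedgraph,
    reproducible_peak_set,
    score_per_million,
    summits_to_candidates,
)
from ataclib.fragments import ChromSizes


def cells_frame(cluster_sizes: dict, samples_per_cluster: dict):
    rows = []
    i = 0
    for cluster, n in cluster_sizes.items():
        samples = samples_per_cluster[cluster]
        for j in range(n):
            rows.append(
                {"barcode": f"bc{i}", "sample": samples[j % len(samples)], "cluster": cluster}
            )
            i += 1
    return pd.DataFrame(rows)


def test_plan_one_replicate_per_qualifying_sample():
    cells = cells_frame({"c1": 300}, {"c1": ["s1", "s2", "s3"]})
    plan = make_pseudobulk_plan(cells, min_cells=40, seed=0)
    reps = plan.replicates["c1"]
    assert len(reps) == 3
    assert all(len(m) == 100 for _, m in reps)
    assert {origin for origin, _ in reps} == {"s1", "s2", "s3"}


def test_plan_subsampled_replicates_for_single_sample_cluster():
    cells = cells_frame({"c1": 60}, {"c1": ["s1"]})
    plan = make_pseudobulk_plan(cells, min_cells=40, sample_ratio=0.8, seed=0)
    reps = plan.replicates["c1"]
    assert len(reps) == 2
    assert all(origin == "subsampled" for origin, _ in reps)
    assert all(len(m) == 48 for _, m in reps)  # 0.8 * 60
    # each replicate drawn without replacement
    for _, m in reps:
        assert len(set(m)) == len(m)


def test_plan_respects_max_cells_and_seed():
    cells = cells_frame({"c1": 1200}, {"c1": ["s1", "s2"]})
    p1 = make_pseudobulk_plan(cells, max_cells=500, seed=3)
    p2 = make_pseudobulk_plan(cells, max_cells=500, seed=3)
    assert p1.replicates == p2.replicates
    assert all(len(m) == 500 for _, m in p1.replicates["c1"])


def test_plan_flags_unsatisfiable_cluster():
    cells = cells_frame({"c1": 10, "c2": 200}, {"c1": ["s1"], "c2": ["s1", "s2"]})
    plan = make_pseudobulk_plan(cells, min_cells=40, seed=0)
    assert plan.flagged == ["c1"]
    with pytest.raises(ValueError, match="no cluster"):
        make_pseudobulk_plan(cells_frame({"c": 5}, {"c": ["s1"]}), min_cells=40)


def test_bedgraph_single_fragment_and_conservation(toy_store):
    frags = pd.DataFrame(
        [("chr1", 100, 200, "A", 1)], columns=["chrom", "start", "end", "barcode", "count"]
    )
    store = toy_store(frags, {"chr1": 1000})
    cov = export_group_coverage(store, {"g": ["A"]})["g"]
    # two unit-height single-base intervals at 100 and 199
    assert len(cov) == 2
    assert cov["value"].tolist() == [1.0, 1.0]
    assert (cov["end"] - cov["start"]).tolist() == [1, 1]
    assert (cov["value"] * (cov["end"] - cov["start"])).sum() == 2 * 1


def test_bedgraph_merges_adjacent_equal_values():
    profile = np.array([0, 2, 2, 2, 0, 1, 1, 3])
    bg = profile_to_bedgraph(profile, "chr1")
    assert bg[["start", "end", "value"]].values.tolist() == [
        [1, 4, 2.0],
        [5, 7, 1.0],
        [7, 8, 3.0],
    ]


def test_summit_caller_on_constructed_profiles():
    flat = np.zeros(5000)
    assert len(call_summits_naive(flat)) == 0
    bump = np.zeros(5000)
    bump[2000:2101] = np.concatenate([np.arange(51), np.arange(50)[::-1]]) * 1.0
    out = call_summits_naive(bump, smoothing_window=25, min_score=1)
    assert len(out) == 1
    assert abs(out["pos"].iloc[0] - 2050) <= 2
    two = np.zeros(6000)
    for c in (1500, 3500):
        two[c - 50 : c + 51] += np.concatenate([np.arange(51), np.arange(50)[::-1]])
    out2 = call_summits_naive(two, smoothing_window=25, min_score=1)
    assert len(out2) == 2
    plateau = np.zeros(3000)
    plateau[1000:1200] = 5.0
    out3 = call_summits_naive(plateau, smoothing_window=25, min_score=1)
    assert len(out3) >= 1
    # leftmost position of the plateau run is reported first
    assert out3["pos"].iloc[0] <= 1100


def test_candidates_extension_and_truncation():
    sizes = ChromSizes({"chr1": 100_000})
    summits = pd.DataFrame({"pos": [1000, 100], "score": [10.0, 5.0]})
    cand = summits_to_candidates(summits, "chr1", sizes, width=501)
    assert (cand.loc[0, "start"], cand.loc[0, "end"]) == (750, 1251)
    assert cand.loc[1, "start"] == 0  # truncated at chromosome start
    with pytest.raises(ValueError, match="odd"):
        summits_to_candidates(summits, "chr1", sizes, width=500)


def test_score_per_million_scale_invariance():
    cand = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 1000], "end": [501, 1501], "summit": [250, 1250],
         "score": [2.0, 6.0]}
    )
    a = score_per_million(cand)
    b = score_per_million(cand.assign(score=cand["score"] * 7.3))
    np.testing.assert_allclose(a["score_per_million"], b["score_per_million"])
    assert a["score_per_million"].sum() == pytest.approx(1e6)


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "score_per_million"])


def test_iterative_merge_hand_trace():
    cand = peak_frame(
        [
            ("chr1", 0, 501, 250, 10.0),
            ("chr1", 250, 751, 500, 8.0),
            ("chr1", 600, 1101, 850, 9.0),
        ]
    )
    out = iterative_overlap_merge(cand)
    assert out["start"].tolist() == [0, 600]  # B discarded: overlaps A
    assert out["n_overlapping"].tolist() == [2, 1]


def test_iterative_merge_identity_and_idempotence(rng):
    starts = np.arange(10) * 1000
    cand = peak_frame(
        [("chr1", int(s), int(s + 501), int(s + 250), float(v)) for s, v in zip(starts, rng.random(10))]
    )
    out = iterative_overlap_merge(cand)
    assert len(out) == 10  # non-overlapping input is untouched
    again = iterative_overlap_merge(out)
    pd.testing.assert_frame_equal(
        out.reset_index(drop=True)[["chrom", "start", "end"]],
        again.reset_index(drop=True)[["chrom", "start", "end"]],
    )


def greedy_oracle(cand: pd.DataFrame) -> list[tuple]:
    """Independent maximum-score-first selection on plain tuples."""
    items = sorted(
        cand.itertuples(index=False),
        key=lambda r: (-r.score_per_million, r.start, r.chrom),
    )
    kept = []
    for r in items:
        if all(
            not (r.chrom == k.chrom and r.start < k.end and r.end > k.start) for k in kept
        ):
            kept.append(r)
    return sorted((k.chrom, k.start, k.end) for k in kept)


def test_merge_matches_exhaustive_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(2, 20))
        starts = rng.integers(0, 3000, size=n)
        cand = peak_frame(
            [
                ("chr1", int(s), int(s + 501), int(s + 250), float(rng.random()))
                for s in starts
            ]
        )
        got = iterative_overlap_merge(cand)
        assert sorted(zip(got["chrom"], got["start"], got["end"])) == greedy_oracle(cand)


def test_reproducible_set_support_filter():
    rep1 = peak_frame([("chr1", 0, 501, 250, 10.0), ("chr1", 2000, 2501, 2250, 5.0)])
    rep2 = peak_frame([("chr1", 10, 511, 260, 9.0)])
    out = reproducible_peak_set({"c1": [rep1, rep2]}, min_rep_support=2)
    # only the first peak is supported by both replicates
    assert len(out) == 1
    assert out["start"].iloc[0] == 0
    assert out["n_replicates_support"].iloc[0] == 2
    identical = reproducible_peak_set({"c1": [rep1, rep1.copy()]}, min_rep_support=2)
    assert len(identical) == 2


def test_global_merge_keeps_higher_scoring_cluster_copy():
    c1 = peak_frame([("chr1", 0, 501, 250, 10.0)])
    c2 = peak_frame([("chr1", 100, 601, 350, 20.0)])
    out = reproducible_peak_set({"a": [c1, c1.copy()], "b": [c2, c2.copy()]})
    assert len(out) == 1
    assert out["group_of_origin"].iloc[0] == "b"


def test_final_peaks_disjoint_fixed_width(dataset, lsi_model):
    from ataclib.lsi import cluster_cells

    labels = cluster_cells(lsi_model.embedding_, 15, 0.8, 7)
    cells = pd.DataFrame(
        {
            "barcode": dataset.tiles.barcodes,
            "sample": dataset.truth["sample"].to_numpy(),
            "cluster": labels,
        }
    )
    plan = make_pseudobulk_plan(cells, min_cells=30, seed=7)
    peaks = call_peaks_from_plan(dataset.store, plan)
    for _, sub in peaks.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
    widths = peaks["end"] - peaks["start"]
    interior = (peaks["start"] > 0) & (peaks["end"] < dataset.chrom_sizes["chr1"])
    assert (widths[interior] == 501).all()
    # planted accessible sites are recovered near called summits
    planted = dataset.sim.peaks
    hits = 0
    for r in planted.itertuples(index=False):
        sub = peaks[peaks["chrom"] == r.chrom]
        if len(sub) and np.abs(sub["summit"].to_numpy() - r.center).min() <= 100:
            hits += 1
    assert hits / len(planted) >= 0.9
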