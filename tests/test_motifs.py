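"""PWM scanning, hypergeometric enrichment, chromVAR deviations."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ataclib.motifs import (
    compute_deviations,
    hypergeom_enrichment,
    positive_tf_regulators,
    pwm_log_odds,
    read_jaspar,
    scan_motifs,
    scan_sequence,
    select_background_peaks,
)

CONS = "TGATAA"


def consensus_pwm(cons=CONS, weight=20.0):
    mat = np.zeros((4, len(cons)))
    for j, b in enumerate(cons):
        mat["ACGT".index(b), j] = weight
    return mat


class DictGenome(dict):
    pass


def revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def test_read_jaspar_formats(tmp_path):
    path = tmp_path / "motifs.txt"
    path.write_text(
        ">M1 FOO\nA [ 1 2 3 ]\nC [4 5 6]\nG [7 8 9]\nT [0 1 0]\n"
        ">M2\nA\t1\t0\nC\t0\t1\nG\t0\t0\nT\t2\t2\n"
    )
    pwms = read_jaspar(path)
    assert set(pwms) == {"M1", "M2"}
    np.testing.assert_array_equal(pwms["M1"][0], [1, 2, 3])
    assert pwms["M2"].shape == (4, 2)


def test_scan_finds_planted_consensus_both_strands(rng):
    bg = "".join(rng.choice(list("ACGT"), size=200))
    seq_fwd = bg[:80] + CONS + bg[80:]
    seq_rev = bg[:120] + revcomp(CONS) + bg[120:]
    genome = DictGenome(chr1=seq_fwd, chr2=seq_rev)
    peaks = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [len(seq_fwd), len(seq_rev)]}
    )
    ann = scan_motifs(peaks, genome, {"tf": consensus_pwm()}, log_odds_threshold=11)
    hits = ann.matches.toarray()
    assert hits[0, 0] == 1 and hits[1, 0] == 1
    pos = ann.positions["tf"]
    strands = pos.groupby("peak_index")["strand"].agg(set)
    assert "+" in strands[0] and "-" in strands[1]


def test_scan_scores_match_brute_force():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    pwm = rng.random((4, 5)) * 10
    lo = pwm_log_odds(pwm)
    fwd, rev = scan_sequence(seq, lo)
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    for p in range(len(seq) - 4):
        window = seq[p : p + 5]
        exp_f = sum(lo[enc[b], j] for j, b in enumerate(window))
        exp_r = sum(lo[enc[b], j] for j, b in enumerate(revcomp(window)))
        assert fwd[p] == pytest.approx(exp_f)
        assert rev[p] == pytest.approx(exp_r)


def test_scan_rejects_out_of_bounds_peak():
    genome = DictGenome(chr1="ACGT" * 10)
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
    with pytest.raises(ValueError, match="beyond"):
        scan_motifs(peaks, genome, {"tf": consensus_pwm()})


def hypergeom_closed_form(N, K, n, k):
    total = sum(
        Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
        for i in range(k, min(K, n) + 1)
    )
    return float(total)


def test_hypergeometric_reference_value():
    ann = np.zeros((100, 1))
    ann[:20] = 1
    selected = np.concatenate([np.arange(5), np.arange(50, 55)])  # k=5 of n=10
    out = hypergeom_enrichment(selected, ann)
    assert out["p_value"].iloc[0] == pytest.approx(hypergeom_closed_form(100, 20, 10, 5), rel=1e-9)
    assert out["p_value"].iloc[0] == pytest.approx(0.025465, abs=1e-5)


def test_hypergeometric_degenerate_cases():
    ann = np.ones((8, 1))
    out = hypergeom_enrichment(np.arange(8), ann)
    assert out["p_value"].iloc[0] == pytest.approx(1.0)  # k = n = K = N
    ann2 = np.zeros((8, 1))
    ann2[:3] = 1
    out2 = hypergeom_enrichment(np.arange(3, 8), ann2)  # k = 0
    assert out2["p_value"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty"):
        hypergeom_enrichment(np.array([], dtype=int), ann)


def test_hypergeometric_matches_closed_form_exhaustively():
    """All configurations with N <= 12 agree with the exact sum."""
    for N in range(2, 13):
        ann = np.zeros((N, 1))
        for K in range(N + 1):
            ann[:] = 0
            ann[:K] = 1
            for n in range(1, N + 1):
                sel = np.arange(n)  # k = min(n, K)
                k = min(n, K)
                out = hypergeom_enrichment(sel, ann)
                assert out["p_value"].iloc[0] == pytest.approx(
                    hypergeom_closed_form(N, K, n, k), rel=1e-9
                ), (N, K, n, k)


def test_background_peaks_matched_and_reproducible(rng):
    gc = rng.uniform(0.3, 0.7, size=300)
    acc = rng.lognormal(0, 1, size=300)
    bg1 = select_background_peaks(gc, acc, n_background=25, seed=4)
    bg2 = select_background_peaks(gc, acc, n_background=25, seed=4)
    np.testing.assert_array_equal(bg1, bg2)
    assert bg1.shape == (300, 25)
    # self excluded; GC matched within 0.05 on average
    for i in range(300):
        assert i not in bg1[i]
    assert np.abs(gc[bg1].mean(axis=1) - gc).mean() < 0.05


def test_deviations_zero_when_counts_proportional_to_depth(rng):
    base = rng.uniform(0.5, 2.0, size=40)
    depth = rng.uniform(0.5, 3.0, size=25)
    X = np.outer(depth, base)
    ann = np.zeros((40, 2))
    ann[rng.choice(40, 12, replace=False), 0] = 1
    ann[:, 1] = 1  # motif covering all peaks
    bg = select_background_peaks(rng.uniform(0, 1, 40), base, n_background=10, seed=0)
    dev = compute_deviations(sp.csr_matrix(X), ann, bg)
    np.testing.assert_allclose(dev.raw, 0.0, atol=1e-10)


def test_z_scores_invariant_to_global_depth_scaling(rng):
    X = rng.poisson(2.0, size=(30, 50)).astype(float) + 1
    ann = np.zeros((50, 1))
    ann[:10] = 1
    bg = select_background_peaks(rng.uniform(0, 1, 50), X.mean(0), n_background=15, seed=1)
    d1 = compute_deviations(sp.csr_matrix(X), ann, bg)
    d2 = compute_deviations(sp.csr_matrix(X * 7.0), ann, bg)
    np.testing.assert_allclose(d1.z, d2.z, atol=1e-8)


def test_random_motif_null_z_distribution(rng):
    """Motifs that are random peak subsets give z-scores with mean ~ 0
    and spread ~ 1 across repeated draws."""
    n_peaks, n_cells = 120, 60
    X = rng.poisson(3.0, size=(n_cells, n_peaks)).astype(float) + 1
    n_draws = 30
    ann = np.zeros((n_peaks, n_draws))
    for j in range(n_draws):
        ann[rng.choice(n_peaks, 30, replace=False), j] = 1
    bg = select_background_peaks(
        rng.uniform(0, 1, n_peaks), X.mean(0), n_background=30, seed=2
    )
    dev = compute_deviations(sp.csr_matrix(X), ann, bg)
    assert abs(dev.z.mean()) < 0.3
    assert 0.5 < dev.z.std() < 2.0


def test_planted_type_specific_motif_elevated(dataset):
    from ataclib.features import build_peak_matrix

    ds = dataset
    pm = build_peak_matrix(
        ds.store,
        ds.sim.peaks[["chrom", "start", "end"]].assign(
            name=[f"p{i}" for i in range(len(ds.sim.peaks))]
        ),
    ).subset_cells(ds.tiles.barcodes)
    pt = pm.features.intervals
    key = {(r.chrom, r.start): i for i, r in enumerate(ds.sim.peaks.itertuples(index=False))}
    planted_order = np.array([key[(r.chrom, r.start)] for r in pt.itertuples(index=False)])
    spec0 = (
        (ds.sim.peaks["cell_type"] == 0) & (ds.sim.peaks["kind"] == "specific")
    ).to_numpy()[planted_order]
    ann = spec0.astype(float)[:, None]
    rng = np.random.default_rng(0)
    acc = np.asarray(pm.counts.mean(axis=0)).ravel()
    bg = select_background_peaks(rng.uniform(0.4, 0.6, len(pt)), acc, n_background=25, seed=0)
    keep = np.asarray(pm.counts.sum(axis=1)).ravel() > 0
    dev = compute_deviations(pm.counts[keep], ann, bg, motif_names=["tf0"])
    types = ds.truth["cell_type"].to_numpy()[keep]
    z0 = dev.z[0, types == 0].mean()
    others = dev.z[0, types != 0].mean()
    assert z0 > 1.0 and z0 > others + 1.0


def test_positive_regulators_identity_and_anticorrelation():
    z = np.array([[1.0, 1.0, 5.0, 5.0, 9.0, 9.0]])
    dev = type("D", (), {"z": z, "motif_names": ["tfA"]})()
    groups = np.array([0, 0, 1, 1, 2, 2])
    expr = pd.DataFrame({"geneA": [1.0, 5.0, 9.0]}, index=[0, 1, 2])
    out = positive_tf_regulators(dev, expr, {"tfA": "geneA"}, groups, correlation_cutoff=0.5)
    assert out["is_positive_regulator"].iloc[0]
    assert out["r"].iloc[0] == pytest.approx(1.0)
    anti = positive_tf_regulators(
        dev, pd.DataFrame({"geneA": [9.0, 5.0, 1.0]}, index=[0, 1, 2]),
        {"tfA": "geneA"}, groups,
    )
    assert not anti["is_positive_regulator"].iloc[0]
    unmapped = positive_tf_regulators(dev, expr, {}, groups)
    assert len(unmapped) == 0
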