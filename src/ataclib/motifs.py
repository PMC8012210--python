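"""Motif annotation, enrichment, and chromVAR-style per-cell deviations.

Peaks are scanned with position weight matrices (JASPAR tab text) by
log-odds against a uniform background on both strands.  Marker-peak
motif enrichment is an upper-tail hypergeometric test.  Per-cell motif
activity is the chromVAR deviation: observed accessibility in a motif's
peaks minus the depth-scaled expectation, corrected and z-scored against
GC/accessibility-matched background peak sets, computed streaming over
cell chunks.  Motif deviations that correlate positively with the TF's
own expression (or gene score) across cell groups nominate positive TF
regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def read_jaspar(path: str | Path) -> dict[str, np.ndarray]:
    """JASPAR-style tab text PWMs: '>name' then one row per base A/C/G/T.

    Rows may be 'A [ 1 2 3 ]' or 'A\t1\t2\t3'.  Returns count matrices of
    shape (4, width) keyed by motif name.
    """
    pwms: dict[str, np.ndarray] = {}
    name, rows = None, {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None and len(rows) == 4:
                pwms[name] = np.array([rows[b] for b in _BASES])
            name = line[1:].split()[0]
            rows = {}
        else:
            base = line[0].upper()
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    if name is not None and len(rows) == 4:
        pwms[name] = np.array([rows[b] for b in _BASES])
    return pwms


def pwm_log_odds(pwm: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Counts -> log-odds vs the 0.25-uniform background."""
    probs = (pwm + pseudocount) / (pwm + pseudocount).sum(axis=0, keepdims=True)
    return np.log2(probs / 0.25)


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def scan_sequence(seq: str, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position log-odds scores on forward and reverse strands."""
    width = log_odds.shape[1]
    enc = _encode(seq)
    n = len(enc) - width + 1
    if n <= 0:
        return np.array([]), np.array([])
    idx = np.arange(width)[None, :] + np.arange(n)[:, None]
    windows = enc[idx]
    valid = (windows >= 0).all(axis=1)
    safe = np.clip(windows, 0, 3)
    fwd = log_odds[safe, np.arange(width)[None, :]].sum(axis=1)
    rc = log_odds[::-1, ::-1]  # reverse complement scoring matrix
    rev = rc[safe, np.arange(width)[None, :]].sum(axis=1)
    fwd[~valid] = -np.inf
    rev[~valid] = -np.inf
    return fwd, rev


@dataclass
class MotifAnnotation:
    """peaks x motifs binary match matrix plus match positions."""

    matches: sp.csr_matrix
    motif_names: list[str]
    positions: dict[str, pd.DataFrame]  # motif -> (peak_index, chrom, pos, strand)


def scan_motifs(
    peaks: pd.DataFrame,
    genome,
    pwms: dict[str, np.ndarray],
    log_odds_threshold: float = 7.0,
) -> MotifAnnotation:
    """Annotate peaks with PWM matches on either strand.

    ``genome`` is a pyfaidx.Fasta-like mapping of chrom -> sliceable
    sequence.  A peak matches when its best per-position log-odds score
    on either strand reaches the threshold; match centres are recorded
    for footprinting.
    """
    names = list(pwms)
    logodds = {m: pwm_log_odds(pwms[m]) for m in names}
    rows, cols = [], []
    positions: dict[str, list] = {m: [] for m in names}
    for i, row in enumerate(peaks.itertuples(index=False)):
        chrom_len = len(genome[row.chrom])
        if row.end > chrom_len or row.start < 0:
            raise ValueError(f"peak {row.chrom}:{row.start}-{row.end} beyond sequence bounds")
        seq = str(genome[row.chrom][row.start : row.end])
        for j, m in enumerate(names):
            fwd, rev = scan_sequence(seq, logodds[m])
            if len(fwd) == 0:
                continue
            width = logodds[m].shape[1]
            hit = False
            for strand, scores in (("+", fwd), ("-", rev)):
                loc = np.flatnonzero(scores >= log_odds_threshold)
                for p in loc:
                    hit = True
                    center = row.start + p + width // 2
                    positions[m].append((i, row.chrom, center, strand))
            if hit:
                rows.append(i)
                cols.append(j)
    matches = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(peaks), len(names))
    )
    pos_frames = {
        m: pd.DataFrame(v, columns=["peak_index", "chrom", "pos", "strand"])
        for m, v in positions.items()
    }
    return MotifAnnotation(matches, names, pos_frames)


def hypergeom_enrichment(
    selected: np.ndarray,
    annotation: sp.spmatrix | np.ndarray,
    motif_names: list[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotations in a peak subset.

    selected: boolean mask or index array over the peak universe.
    annotation: peaks x annotations binary matrix.  p = P(X >= k) with
    k = |annotated ∩ selected|, K = |annotated|, n = |selected|,
    N = |universe|; BH adjustment across annotations.  Also applicable to
    arbitrary region-set overlap columns.
    """
    A = sp.csr_matrix(annotation)
    N = A.shape[0]
    mask = np.zeros(N, dtype=bool)
    mask[selected] = True
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty selection")
    K = np.asarray(A.sum(axis=0)).ravel()
    k = np.asarray(A[mask].sum(axis=0)).ravel()
    p = stats.hypergeom.sf(k - 1, N, K.astype(int), n)
    adj = multipletests(p, method="fdr_bh")[1]
    expected = K * n / N
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, k / expected, np.nan)
    return pd.DataFrame(
        {
            "motif": motif_names if motif_names is not None else np.arange(A.shape[1]),
            "n_selected": n,
            "n_annotated": K.astype(int),
            "n_overlap": k.astype(int),
            "p_value": p,
            "fdr": adj,
            "fold_enrichment": fold,
        }
    )


def select_background_peaks(
    gc_fraction: np.ndarray,
    mean_accessibility: np.ndarray,
    n_background: int = 50,
    n_neighbors: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-peak background sets matched on (GC, log1p mean accessibility).

    Both covariates are standardised; for each peak, ``n_background``
    peaks are sampled with replacement from its ``n_neighbors`` nearest
    peaks in that space, excluding the peak itself.  Returns an integer
    array of shape (n_peaks, n_background).
    """
    n_peaks = len(gc_fraction)
    if n_peaks < n_background + 1:
        raise ValueError("need more peaks than n_background")
    feats = np.column_stack([gc_fraction, np.log1p(mean_accessibility)])
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / std
    k = min(n_neighbors + 1, n_peaks)
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    _, idx = nn.kneighbors(feats)
    rng = np.random.default_rng(seed)
    out = np.empty((n_peaks, n_background), dtype=np.int64)
    for i in range(n_peaks):
        cand = idx[i][idx[i] != i]
        out[i] = rng.choice(cand, size=n_background, replace=True)
    return out


@dataclass
class DeviationResult:
    """motifs x cells deviations: raw, background-corrected, and z-scores."""

    raw: np.ndarray
    deviations: np.ndarray
    z: np.ndarray
    motif_names: list[str]


def compute_deviations(
    peak_matrix,
    annotation: sp.spmatrix | np.ndarray,
    backgrounds: np.ndarray,
    motif_names: list[str] | None = None,
    chunk_size: int = 2000,
) -> DeviationResult:
    """chromVAR deviations, streamed over cell chunks.

    expected(cell, motif) = depth_cell * sum(counts in motif peaks over
    all cells) / total counts; raw = (obs - exp) / exp.  The corrected
    deviation subtracts the mean raw deviation over the peak-matched
    background sets and z-scores by their standard deviation.
    """
    from .features import FeatureMatrix

    X = peak_matrix.counts if isinstance(peak_matrix, FeatureMatrix) else sp.csr_matrix(peak_matrix)
    X = sp.csr_matrix(X, dtype=np.float64)
    n_cells, n_peaks = X.shape
    A = sp.csr_matrix(annotation, dtype=np.float64)
    if A.shape[0] != n_peaks:
        raise ValueError("annotation rows must match peak matrix columns")
    depth = np.asarray(X.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("zero-depth cells present; filter before computing deviations")
    peak_totals = np.asarray(X.sum(axis=0)).ravel()
    grand = peak_totals.sum()
    frac = peak_totals / grand  # expected share of a cell's counts per peak

    n_motifs = A.shape[1]
    n_bg = backgrounds.shape[1]
    # background annotation matrices: same motif membership pattern but
    # peaks swapped for their matched background peak (iteration b)
    motif_frac = np.asarray(A.T @ frac).ravel()  # per motif expected share
    raw_all = np.empty((n_motifs, n_cells))
    bg_mean = np.zeros((n_motifs, n_cells))
    bg_m2 = np.zeros((n_motifs, n_cells))
    for start in range(0, n_cells, chunk_size):
        stop = min(start + chunk_size, n_cells)
        Xc = X[start:stop]
        d = depth[start:stop]
        obs = np.asarray((Xc @ A).todense()).T  # motifs x chunk
        exp = np.outer(motif_frac, d)
        raw = (obs - exp) / np.where(exp == 0, 1.0, exp)
        raw_all[:, start:stop] = raw
    for b in range(n_bg):
        # permuted annotation: peak p's membership moves to backgrounds[p, b]
        Ab = sp.csr_matrix(
            (A.tocoo().data, (backgrounds[A.tocoo().row, b], A.tocoo().col)), shape=A.shape
        )
        bfrac = np.asarray(Ab.T @ frac).ravel()
        for start in range(0, n_cells, chunk_size):
            stop = min(start + chunk_size, n_cells)
            Xc = X[start:stop]
            d = depth[start:stop]
            obs = np.asarray((Xc @ Ab).todense()).T
            exp = np.outer(bfrac, d)
            raw = (obs - exp) / np.where(exp == 0, 1.0, exp)
            bg_mean[:, start:stop] += raw
            bg_m2[:, start:stop] += raw**2
    bg_mean /= n_bg
    bg_sd = np.sqrt(np.maximum(bg_m2 / n_bg - bg_mean**2, 0))
    corrected = raw_all - bg_mean
    z = corrected / np.where(bg_sd == 0, 1.0, bg_sd)
    names = motif_names if motif_names is not None else [str(i) for i in range(n_motifs)]
    return DeviationResult(raw_all, corrected, z, list(names))


def positive_tf_regulators(
    deviations: DeviationResult,
    expression_by_group: pd.DataFrame,
    motif_to_gene: dict[str, str],
    groups: np.ndarray,
    correlation_cutoff: float = 0.5,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """TFs whose expression tracks their motif deviation across groups.

    ``expression_by_group``: groups x genes mean expression (or gene
    scores).  Motif z-scores are averaged per group, correlated with the
    mapped gene's expression; TFs with r > cutoff and BH-adjusted p <=
    fdr_cutoff are flagged.
    """
    groups = np.asarray(groups)
    uniq = sorted(expression_by_group.index)
    z_by_group = np.vstack(
        [deviations.z[:, groups == g].mean(axis=1) for g in uniq]
    )  # groups x motifs
    records = []
    for j, motif in enumerate(deviations.motif_names):
        gene = motif_to_gene.get(motif)
        if gene is None or gene not in expression_by_group.columns:
            logger.info("motif %s has no mapped/measured gene; excluded", motif)
            continue
        e = expression_by_group.loc[uniq, gene].to_numpy(float)
        zv = z_by_group[:, j]
        if e.std() == 0 or zv.std() == 0:
            continue
        r, p = stats.pearsonr(zv, e)
        records.append({"motif": motif, "gene": gene, "r": r, "p_value": p})
    if not records:
        return pd.DataFrame(columns=["motif", "gene", "r", "p_value", "fdr", "is_positive_regulator"])
    out = pd.DataFrame(records)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_positive_regulator"] = (out["r"] > correlation_cutoff) & (out["fdr"] <= fdr_cutoff)
    return out
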