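"""Pseudo-bulk replicates and fixed-width reproducible peak calling.

Per-cluster, sample-aware pseudo-bulk replicates preserve biological
variability; each replicate's insertion coverage yields summits (via an
internal smoothed local-maximum caller, or imported MACS2 summit BEDs),
summits become fixed-width candidates (501 bp) with score-per-million
normalised significance, and an iterative overlap-merging procedure —
greedily keep the best-scoring candidate, discard everything overlapping
it — produces a non-overlapping peak set, first within clusters (with a
replicate-support filter) and then globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentStore

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pseudo-bulk replicates
# ---------------------------------------------------------------------------

@dataclass
class PseudoBulkPlan:
    """cluster -> list of replicates; each replicate is (origin, barcodes)."""

    replicates: dict[str, list[tuple[str, list[str]]]] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)


def make_pseudobulk_plan(
    cells: pd.DataFrame,
    min_cells: int = 40,
    max_cells: int = 500,
    min_replicates: int = 2,
    sample_ratio: float = 0.8,
    seed: int = 0,
) -> PseudoBulkPlan:
    """Sample-aware replicate assignment per cluster.

    Samples contributing at least ``min_cells`` to a cluster each become a
    replicate (subsampled to ``max_cells``).  Clusters with fewer than
    ``min_replicates`` qualifying samples fall back to subsampled
    replicates of ``sample_ratio`` of the cluster's cells, drawn without
    replacement within each replicate and minimising reuse across
    replicates.  Clusters that cannot reach ``min_replicates * min_cells``
    members are flagged and skipped.
    """
    if not {"barcode", "sample", "cluster"}.issubset(cells.columns):
        raise ValueError("cells table needs barcode, sample, cluster columns")
    rng = np.random.default_rng(seed)
    plan = PseudoBulkPlan()
    for cluster, sub in cells.groupby("cluster", sort=True):
        cluster = str(cluster)
        reps: list[tuple[str, list[str]]] = []
        by_sample = {s: g["barcode"].tolist() for s, g in sub.groupby("sample", sort=True)}
        qualifying = {s: b for s, b in by_sample.items() if len(b) >= min_cells}
        if len(qualifying) >= min_replicates:
            for s, bcs in qualifying.items():
                if len(bcs) > max_cells:
                    bcs = list(rng.choice(bcs, size=max_cells, replace=False))
                reps.append((s, sorted(bcs)))
        else:
            all_bcs = np.array(sorted(sub["barcode"]))
            size = min(int(round(sample_ratio * len(all_bcs))), max_cells)
            if size * 1 < min_cells or len(all_bcs) < min_cells:
                plan.flagged.append(cluster)
                continue
            used = np.zeros(len(all_bcs))
            for r in range(min_replicates):
                # favour least-used cells to minimise reuse across replicates
                priority = used + rng.random(len(all_bcs))
                pick = np.argsort(priority, kind="stable")[:size]
                used[pick] += 1
                reps.append(("subsampled", sorted(all_bcs[pick].tolist())))
            overlap = int((used > 1).sum())
            if overlap:
                logger.info("cluster %s: %d cells reused across replicates", cluster, overlap)
        if len(reps) < min_replicates:
            plan.flagged.append(cluster)
            continue
        plan.replicates[cluster] = reps
    if not plan.replicates:
        raise ValueError("no cluster satisfies the pseudo-bulk replicate requirements")
    return plan


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def group_insertion_profile(
    store: FragmentStore, barcodes: list[str], chrom: str
) -> np.ndarray:
    """Per-base insertion weight for a cell group on one chromosome."""
    length = store.chrom_sizes[chrom]
    profile = np.zeros(length)
    index = store.global_barcode_index()
    wanted = np.zeros(len(index), dtype=bool)
    for b in barcodes:
        wanted[index[b]] = True
    ins = store.insertion_arrays(chrom)
    keep = wanted[ins["bid"]]
    np.add.at(profile, ins["pos"][keep], ins["weight"][keep])
    return profile


def profile_to_bedgraph(profile: np.ndarray, chrom: str) -> pd.DataFrame:
    """Canonical bedGraph: maximal runs of equal non-zero value."""
    change = np.flatnonzero(np.diff(profile) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(profile)]])
    vals = profile[starts]
    keep = vals != 0
    return pd.DataFrame(
        {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": vals[keep]}
    )


def export_group_coverage(
    store: FragmentStore, groups: dict[str, list[str]]
) -> dict[str, pd.DataFrame]:
    """Per-group bedGraph of per-base insertion counts over all chromosomes."""
    out = {}
    for name, barcodes in groups.items():
        if not barcodes:
            raise ValueError(f"group {name!r} is empty")
        parts = []
        for chrom in store.chrom_sizes.names:
            prof = group_insertion_profile(store, barcodes, chrom)
            parts.append(profile_to_bedgraph(prof, chrom))
        out[name] = pd.concat(parts, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# summit calling
# ---------------------------------------------------------------------------

def call_summits_naive(
    profile: np.ndarray, smoothing_window: int = 75, min_score: float = 1.0
) -> pd.DataFrame:
    """Local maxima of the moving-average-smoothed insertion profile.

    A position is a summit if its smoothed value is >= ``min_score``, is
    not exceeded anywhere within ``smoothing_window`` bases, and — on
    plateaus of equal value — is the leftmost such position.  The later
    overlap merge enforces the minimum summit separation.
    """
    if (profile < 0).any():
        raise ValueError("profile must be non-negative")
    if profile.max() == 0:
        return pd.DataFrame(columns=["pos", "score"])
    w = smoothing_window
    kernel = np.ones(w) / w
    smoothed = np.convolve(profile, kernel, mode="same")
    from scipy.ndimage import maximum_filter1d

    local_max = maximum_filter1d(smoothed, size=2 * w + 1, mode="nearest")
    is_peak = (smoothed >= min_score) & (smoothed == local_max)
    pos = np.flatnonzero(is_peak)
    if len(pos) == 0:
        return pd.DataFrame(columns=["pos", "score"])
    # plateau tie-break: keep the leftmost of each equal-valued run within
    # the window; drop the rest
    kept_pos = []
    last = -(10**12)
    last_val = None
    for p in pos:
        if p - last <= 2 * w and smoothed[p] == last_val:
            continue
        kept_pos.append(p)
        last = p
        last_val = smoothed[p]
    pos = np.array(kept_pos)
    return pd.DataFrame({"pos": pos, "score": smoothed[pos]})


def summits_to_candidates(
    summits: pd.DataFrame,
    chrom: str,
    chrom_sizes,
    width: int = 501,
) -> pd.DataFrame:
    """Extend summits +/-(width-1)/2, truncate at chromosome bounds."""
    if width % 2 == 0:
        raise ValueError("peak width must be odd")
    half = (width - 1) // 2
    length = chrom_sizes[chrom]
    start = np.maximum(summits["pos"].to_numpy(np.int64) - half, 0)
    end = np.minimum(summits["pos"].to_numpy(np.int64) + half + 1, length)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "summit": summits["pos"].to_numpy(np.int64),
            "score": summits["score"].to_numpy(float),
        }
    )


def score_per_million(candidates: pd.DataFrame) -> pd.DataFrame:
    """Normalise one replicate's summit scores to parts-per-million."""
    out = candidates.copy()
    total = out["score"].sum()
    out["score_per_million"] = out["score"] / total * 1e6 if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# iterative overlap merging
# ---------------------------------------------------------------------------

def iterative_overlap_merge(candidates: pd.DataFrame, score_col: str = "score_per_million") -> pd.DataFrame:
    """Greedy rank-by-significance selection of non-overlapping peaks.

    Repeatedly keep the highest-scoring remaining candidate and discard
    every candidate sharing >= 1 base with it.  Ties break by earlier
    start, then chromosome name.  The kept set is returned sorted by
    coordinate with ``n_overlapping``, the number of discarded candidates
    (plus itself) that overlapped each kept peak.
    """
    if len(candidates) == 0:
        return candidates.assign(n_overlapping=pd.Series(dtype=int))
    df = candidates.sort_values(
        [score_col, "start", "chrom"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    kept_rows = []
    n_overlap = []
    active = np.ones(len(df), dtype=bool)
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for i in range(len(df)):
        if not active[i]:
            continue
        overlap = active & (chroms == chroms[i]) & (starts < ends[i]) & (ends > starts[i])
        kept_rows.append(i)
        n_overlap.append(int(overlap.sum()))
        active[overlap] = False
    out = df.iloc[kept_rows].copy()
    out["n_overlapping"] = n_overlap
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _support_counts(kept: pd.DataFrame, replicate_candidates: list[pd.DataFrame]) -> np.ndarray:
    """Number of replicates with >= 1 candidate overlapping each kept peak."""
    support = np.zeros(len(kept), dtype=int)
    for rep in replicate_candidates:
        hit = np.zeros(len(kept), dtype=bool)
        for chrom, sub in rep.groupby("chrom"):
            mask = kept["chrom"].to_numpy() == chrom
            if not mask.any():
                continue
            ks = kept["start"].to_numpy()[mask]
            ke = kept["end"].to_numpy()[mask]
            rs = np.sort(sub["start"].to_numpy())
            re = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy(), kind="stable")]
            # any replicate candidate overlapping [ks, ke)?
            j = np.searchsorted(rs, ke, side="left")
            prev_max_end = np.maximum.accumulate(re) if len(re) else re
            has = (j > 0) & (prev_max_end[np.clip(j - 1, 0, None)] > ks)
            hit[np.flatnonzero(mask)] |= has
        support += hit
    return support


def reproducible_peak_set(
    per_replicate: dict[str, list[pd.DataFrame]],
    min_rep_support: int = 2,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster-wise then global iterative overlap merge.

    ``per_replicate`` maps cluster -> list of per-replicate candidate
    tables (with score_per_million).  Within each cluster, candidates are
    merged and peaks supported by >= ``min_rep_support`` replicates kept;
    cluster sets are then merged globally, recording the winning cluster.
    Peaks overlapping an optional blacklist are removed before merging.
    """
    cluster_sets = []
    for cluster, reps in per_replicate.items():
        pooled = pd.concat(reps, ignore_index=True)
        if blacklist is not None and len(blacklist):
            pooled = _remove_blacklisted(pooled, blacklist)
        merged = iterative_overlap_merge(pooled)
        support = _support_counts(merged, reps)
        merged = merged[support >= min_rep_support].copy()
        merged["n_replicates_support"] = support[support >= min_rep_support]
        merged["group_of_origin"] = cluster
        cluster_sets.append(merged)
    all_peaks = pd.concat(cluster_sets, ignore_index=True)
    final = iterative_overlap_merge(all_peaks)
    return final.reset_index(drop=True)


def _remove_blacklisted(candidates: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    keep = np.ones(len(candidates), dtype=bool)
    for chrom, sub in blacklist.groupby("chrom"):
        mask = candidates["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        cs = candidates["start"].to_numpy()[mask]
        ce = candidates["end"].to_numpy()[mask]
        for bs, be in zip(sub["start"], sub["end"]):
            keep[np.flatnonzero(mask)[(cs < be) & (ce > bs)]] = False
    return candidates[keep].reset_index(drop=True)


def add_gc_fraction(peaks: pd.DataFrame, genome) -> pd.DataFrame:
    """Annotate peaks with GC fraction from a pyfaidx Fasta-like genome."""
    gc = []
    for row in peaks.itertuples(index=False):
        seq = str(genome[row.chrom][row.start : row.end]).upper()
        gc.append((seq.count("G") + seq.count("C")) / max(len(seq), 1))
    out = peaks.copy()
    out["gc_fraction"] = gc
    return out


def peaks_to_bed(peaks: pd.DataFrame, path: str) -> None:
    """BED6+: name = origin cluster, score = score-per-million x 10 capped
    at 1000, strand '.', then summit / support columns."""
    df = peaks.copy()
    score = np.minimum(df["score_per_million"] * 10, 1000).round().astype(int)
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            name = getattr(row, "group_of_origin", "peak")
            extra = f"\t{row.summit}\t{getattr(row, 'n_replicates_support', 0)}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score[i]}\t.{extra}\n"
            )


def call_peaks_from_plan(
    store: FragmentStore,
    plan: PseudoBulkPlan,
    width: int = 501,
    smoothing_window: int = 75,
    min_score: float = 1.0,
    min_rep_support: int = 2,
    blacklist: pd.DataFrame | None = None,
    summit_files: dict[str, list[pd.DataFrame]] | None = None,
) -> pd.DataFrame:
    """End-to-end: coverage -> summits -> candidates -> reproducible set.

    ``summit_files`` (cluster -> per-replicate summit tables with
    chrom/pos/score, e.g. imported MACS2 summits) bypasses the internal
    caller when given.
    """
    chrom_sizes = store.chrom_sizes
    per_replicate: dict[str, list[pd.DataFrame]] = {}
    for cluster, reps in plan.replicates.items():
        tables = []
        for r, (_origin, barcodes) in enumerate(reps):
            if summit_files is not None:
                summits_all = summit_files[cluster][r]
                cand = pd.concat(
                    [
                        summits_to_candidates(sub[["pos", "score"]], chrom, chrom_sizes, width)
                        for chrom, sub in summits_all.groupby("chrom")
                    ],
                    ignore_index=True,
                )
            else:
                parts = []
                for chrom in chrom_sizes.names:
                    prof = group_insertion_profile(store, barcodes, chrom)
                    summits = call_summits_naive(prof, smoothing_window, min_score)
                    if len(summits):
                        parts.append(summits_to_candidates(summits, chrom, chrom_sizes, width))
                cand = (
                    pd.concat(parts, ignore_index=True)
                    if parts
                    else pd.DataFrame(columns=["chrom", "start", "end", "summit", "score"])
                )
            tables.append(score_per_million(cand))
        per_replicate[cluster] = tables
    return reproducible_peak_set(per_replicate, min_rep_support, blacklist)
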