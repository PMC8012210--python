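"""Per-cell quality control: TSS enrichment, fragment counts, size histograms.

The TSS enrichment score is the standard per-cell quality metric: Tn5
insertions are aggregated into a strand-oriented profile around all
annotated transcription start sites, and the score is the ratio of mean
per-base insertion density in a centered window to that in the two outer
flank windows.  High-quality nuclei concentrate insertions at TSSs; the
score separates them cleanly from ambient/low-quality barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentStore

PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class TSSParams:
    """Windows for the TSS enrichment score.

    window : bases on each side of the TSS used for the profile.
    center_width : width of the centered signal window (odd, default 101).
    flank_width : bases at each outer edge used as background.
    """

    window: int = 2000
    center_width: int = 101
    flank_width: int = 100

    def __post_init__(self) -> None:
        if self.center_width >= 2 * self.window:
            raise ValueError("center_width must be < 2*window")
        if self.flank_width > self.window:
            raise ValueError("flank_width must be <= window")


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read TSS positions from BED6 (start column is the TSS; strand used)."""
    df = pd.read_csv(path, sep="\t", header=None)
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "pos": df[1].astype(int),
            "strand": df[5].astype(str) if df.shape[1] >= 6 else "+",
        }
    )
    return out


def tss_enrichment(
    store: FragmentStore,
    tss: pd.DataFrame,
    params: TSSParams = TSSParams(),
) -> pd.Series:
    """Per-barcode TSS enrichment score.

    For each cell, insertions falling within ``params.window`` of any TSS
    are assigned a strand-oriented offset (minus-strand TSS profiles are
    reversed, preserving upstream/downstream asymmetry).  The score is

        (mean center insertions + 0.1) / (mean flank insertions + 0.1)

    with means per base over the aggregated profile; cells with no
    insertions near any TSS score 0.
    """
    chrom_sizes = store.chrom_sizes
    usable = tss[
        tss["chrom"].isin(chrom_sizes.names)
        & (tss["pos"] >= params.window)
        & (tss["pos"].to_numpy() + params.window <= tss["chrom"].map(chrom_sizes.sizes).to_numpy())
    ]
    if len(usable) == 0:
        raise ValueError("no usable TSS after windowing against chromosome bounds")

    barcodes = store.barcodes()
    center_sum = np.zeros(len(barcodes))
    flank_sum = np.zeros(len(barcodes))
    any_hit = np.zeros(len(barcodes), dtype=bool)

    half_center = (params.center_width - 1) // 2
    w = params.window
    for chrom, group in usable.groupby("chrom"):
        ins = store.insertion_arrays(chrom)
        pos, weight, bc_ids = ins["pos"], ins["weight"], ins["bid"]
        if len(pos) == 0:
            continue
        for site, strand in zip(group["pos"].to_numpy(), group["strand"].to_numpy()):
            lo = np.searchsorted(pos, site - w, side="left")
            hi = np.searchsorted(pos, site + w, side="right")
            if lo == hi:
                continue
            off = pos[lo:hi] - site
            if strand == "-":
                off = -off
            sub_w = weight[lo:hi]
            sub_b = bc_ids[lo:hi]
            in_center = np.abs(off) <= half_center
            in_flank = np.abs(off) > w - params.flank_width
            np.add.at(center_sum, sub_b[in_center], sub_w[in_center])
            np.add.at(flank_sum, sub_b[in_flank], sub_w[in_flank])
            any_hit[sub_b] = True

    center_mean = center_sum / params.center_width
    flank_mean = flank_sum / (2 * params.flank_width)
    score = (center_mean + PSEUDOCOUNT) / (flank_mean + PSEUDOCOUNT)
    score[~any_hit] = 0.0
    return pd.Series(score, index=barcodes, name="tss_enrichment")


def fragment_size_histogram(store: FragmentStore, max_size: int = 1000) -> pd.DataFrame:
    """Per-sample histogram of fragment sizes from 1 to ``max_size`` bp."""
    per_sample = {s: np.zeros(max_size) for s in store.samples}
    for sample, _chrom, block in store._iter_blocks():
        size = block["length"]
        keep = (size >= 1) & (size <= max_size)
        np.add.at(per_sample[sample], size[keep] - 1, block["count"][keep].astype(float))
    rows = [
        pd.DataFrame({"sample": s, "size": np.arange(1, max_size + 1), "weight": c})
        for s, c in per_sample.items()
    ]
    return pd.concat(rows, ignore_index=True)


def compute_cell_qc(
    store: FragmentStore,
    tss: pd.DataFrame,
    params: TSSParams = TSSParams(),
) -> pd.DataFrame:
    """CellQC table: one row per barcode with n_frags and tss_enrichment."""
    n_frags = store.fragment_counts()
    scores = tss_enrichment(store, tss, params)
    sample_of = store.barcode_sample()
    qc = pd.DataFrame(
        {
            "barcode": n_frags.index,
            "sample": [sample_of[b] for b in n_frags.index],
            "n_frags": n_frags.to_numpy(),
            "tss_enrichment": scores.reindex(n_frags.index).fillna(0.0).to_numpy(),
        }
    )
    qc["pass_qc"] = False
    return qc.reset_index(drop=True)


def filter_cells(qc: pd.DataFrame, min_tss: float = 4.0, min_frags: float = 1000) -> pd.DataFrame:
    """Mark and return cells passing both inclusive QC thresholds."""
    if min_tss < 0 or min_frags < 0:
        raise ValueError("thresholds must be non-negative")
    qc = qc.copy()
    qc["pass_qc"] = (qc["tss_enrichment"] >= min_tss) & (qc["n_frags"] >= min_frags)
    kept = qc[qc["pass_qc"]]
    if len(kept) == 0:
        raise ValueError(
            f"no cells pass QC at min_tss={min_tss}, min_frags={min_frags}; lower the thresholds"
        )
    return qc


def fraction_in_regions(store: FragmentStore, regions: pd.DataFrame) -> pd.Series:
    """Optional metric: fraction of each cell's insertions inside regions.

    ``regions`` needs chrom/start/end columns (e.g. promoters). Reported
    for inspection; not used by :func:`filter_cells`.
    """
    barcodes = store.barcodes()
    inside = np.zeros(len(barcodes))
    total = np.zeros(len(barcodes))
    for chrom in store.chrom_sizes.names:
        ins = store.insertion_arrays(chrom)
        pos, w, ids = ins["pos"], ins["weight"], ins["bid"]
        if len(pos) == 0:
            continue
        np.add.at(total, ids, w)
        sub = regions[regions["chrom"] == chrom]
        if len(sub) == 0:
            continue
        order = np.argsort(sub["start"].to_numpy())
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        np.add.at(inside, ids[hit], w[hit])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, inside / total, 0.0)
    return pd.Series(frac, index=barcodes, name="frac_in_regions")
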