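"""Sparse cells x features matrices over genomic interval feature sets.

Before peaks exist, analysis runs on a genome-wide tile matrix of
fixed-width bins (500 bp by default); after peak calling, on a peak
matrix.  Both count Tn5 insertions, are built chromosome block by
chromosome block, and are stored as scipy CSR with an interval-addressed
feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fragments import FragmentStore


@dataclass
class FeatureSet:
    """Interval-addressed features: tiles, peaks, or genes.

    ``intervals`` is a DataFrame with chrom/start/end (half-open) and a
    ``name`` column; within each chromosome intervals are sorted by start.
    """

    intervals: pd.DataFrame
    kind: str = "tile"

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "name"}
        if not req.issubset(self.intervals.columns):
            raise ValueError(f"feature intervals need columns {sorted(req)}")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def names(self) -> list[str]:
        return list(self.intervals["name"])


@dataclass
class FeatureMatrix:
    """Cells x features counts with feature metadata.

    counts: CSR, shape (n_barcodes, n_features), all entries >= 0.
    """

    barcodes: list[str]
    features: FeatureSet
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise ValueError("matrix dimensions inconsistent with barcodes/features")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depth(self) -> np.ndarray:
        """Per-cell total counts."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, barcodes: list[str]) -> "FeatureMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = [index[b] for b in barcodes]
        return FeatureMatrix(list(barcodes), self.features, self.counts[rows].tocsr())


def tile_features(chrom_sizes, tile_size: int = 500) -> FeatureSet:
    """All genome tiles: ceil(length / tile_size) per chromosome; the
    terminal tile is truncated at the chromosome end."""
    rows = []
    for chrom in chrom_sizes.names:
        length = chrom_sizes[chrom]
        n = -(-length // tile_size)
        starts = np.arange(n, dtype=np.int64) * tile_size
        ends = np.minimum(starts + tile_size, length)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "name": [f"{chrom}:{s}-{e}" for s, e in zip(starts, ends)],
                }
            )
        )
    return FeatureSet(pd.concat(rows, ignore_index=True), kind="tile")


def build_tile_matrix(
    store: FragmentStore, tile_size: int = 500, binarize: bool = False
) -> FeatureMatrix:
    """Genome-wide insertion-count tile matrix.

    An insertion at position p lands in tile floor(p / tile_size); both
    ends of each fragment count, weighted by the duplicate count, so tile
    column sums conserve twice the per-cell fragment weight.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    chrom_sizes = store.chrom_sizes
    feats = tile_features(chrom_sizes, tile_size)
    barcodes = store.barcodes()
    n_cells = len(barcodes)
    blocks = []
    for chrom in chrom_sizes.names:
        n_tiles = -(-chrom_sizes[chrom] // tile_size)
        ins = store.insertion_arrays(chrom)
        tile_idx = ins["pos"] // tile_size
        block = sp.coo_matrix(
            (ins["weight"], (ins["bid"], tile_idx)), shape=(n_cells, n_tiles)
        ).tocsr()
        blocks.append(block)
    counts = sp.hstack(blocks, format="csr")
    if binarize:
        counts.data = np.ones_like(counts.data)
    return FeatureMatrix(barcodes, feats, counts)


def count_in_intervals(
    store: FragmentStore, intervals: pd.DataFrame, n_cells: int
) -> sp.csr_matrix:
    """Insertion counts of each cell in each (disjoint, sorted) interval."""
    cols = []
    rows = []
    vals = []
    offset = 0
    for chrom in store.chrom_sizes.names:
        sub = intervals[intervals["chrom"] == chrom]
        if len(sub):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            ins = store.insertion_arrays(chrom)
            if len(ins["pos"]):
                idx = np.searchsorted(starts, ins["pos"], side="right") - 1
                hit = (idx >= 0) & (ins["pos"] < ends[np.clip(idx, 0, None)])
                rows.append(ins["bid"][hit])
                cols.append(idx[hit] + offset)
                vals.append(ins["weight"][hit])
        offset += len(sub)
    if not rows:
        return sp.csr_matrix((n_cells, offset))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cells, offset),
    )


def build_peak_matrix(store: FragmentStore, peaks: "FeatureSet | pd.DataFrame") -> FeatureMatrix:
    """Cells x peaks insertion counts.

    Peaks must be non-overlapping (the iterative overlap merge guarantees
    this); overlap raises.  Interval membership is half-open: an insertion
    at the peak ``end`` coordinate is not counted.
    """
    intervals = peaks.intervals if isinstance(peaks, FeatureSet) else peaks
    intervals = (
        intervals.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    )
    for _, sub in intervals.groupby("chrom"):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError("peaks overlap; run iterative overlap merging first")
    barcodes = store.barcodes()
    counts = count_in_intervals(store, intervals, len(barcodes))
    if "name" not in intervals.columns:
        intervals = intervals.assign(
            name=[f"{c}:{s}-{e}" for c, s, e in zip(intervals["chrom"], intervals["start"], intervals["end"])]
        )
    return FeatureMatrix(barcodes, FeatureSet(intervals, kind="peak"), counts)


def write_mtx(matrix: FeatureMatrix, prefix: str) -> None:
    """Export as MatrixMarket triple: matrix.mtx, barcodes.tsv, features.tsv."""
    from scipy.io import mmwrite

    mmwrite(f"{prefix}.mtx", matrix.counts.T.tocoo())  # features x cells, 10x style
    pd.Series(matrix.barcodes).to_csv(f"{prefix}.barcodes.tsv", index=False, header=False)
    matrix.features.intervals.to_csv(f"{prefix}.features.tsv", sep="\t", index=False)
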