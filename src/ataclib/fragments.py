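"""Disk-backed fragment storage.

Fragment files (the 10x ``fragments.tsv`` dialect: chrom, start, end,
barcode and an optional duplicate count) are parsed into an HDF5 container
laid out as one group per sample and one block of parallel integer arrays
per chromosome.  Blocks are sorted by start coordinate, so region queries
touch a single chromosome block and never require loading the whole file.

Coordinates are 0-based half-open throughout.  Tn5 +4/-5 offsets are
assumed to have been applied upstream; no additional shift is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


class FragmentFileError(ValueError):
    """Raised for malformed fragment input."""


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome names and lengths.

    Parameters
    ----------
    sizes
        Mapping of chromosome name to length in bases.  Lengths must be
        positive and names unique (guaranteed by the mapping type).
    """

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        if df["chrom"].duplicated().any():
            raise ValueError("duplicate chromosome names in chrom sizes file")
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return int(self.sizes[chrom])

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")


def read_fragments_tsv(path: str | Path) -> pd.DataFrame:
    """Read a fragments TSV (plain or gzip) into a DataFrame.

    The file must have at least four tab-separated columns
    (chrom, start, end, barcode); a fifth duplicate-count column defaults
    to 1 when absent.  Malformed lines raise with the 1-based line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            dtype={0: str, 3: str},
            on_bad_lines="error",
        )
    except Exception as exc:  # pandas wraps line info in the message
        raise FragmentFileError(f"failed to parse fragment file {path}: {exc}") from exc
    # leading '#' header lines (barcodes themselves may contain '#')
    df = df[~df[0].str.startswith("#")].reset_index(drop=True)
    if df.shape[1] < 4:
        raise FragmentFileError(f"{path}: expected >= 4 tab-separated columns, got {df.shape[1]}")
    df = df.iloc[:, :5].copy()
    if df.shape[1] == 4:
        df[4] = 1
    df.columns = _FRAGMENT_COLUMNS
    for col in ("start", "end", "count"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FragmentFileError(f"{path}: malformed {col} field at line {line}") from exc
    bad = (df["start"] < 0) | (df["end"] <= df["start"]) | (df["count"] < 1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FragmentFileError(f"{path}: invalid fragment interval/count at line {line}")
    return df


class FragmentStore:
    """Chunked, random-access container of barcoded fragments.

    One HDF5 group per sample; within a sample one block per chromosome
    holding parallel arrays (start, length, barcode id, count) sorted by
    start.  A per-sample barcode dictionary maps barcode ids to strings.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)

    # -- construction -------------------------------------------------
    @classmethod
    def create(cls, path: str | Path, chrom_sizes: ChromSizes) -> "FragmentStore":
        store = cls(path, mode="w")
        grp = store._h5.create_group("chrom_sizes")
        grp.create_dataset("name", data=np.array(chrom_sizes.names, dtype="S"))
        grp.create_dataset(
            "length", data=np.array([chrom_sizes[c] for c in chrom_sizes.names], dtype=np.int64)
        )
        store._h5.create_group("samples")
        return store

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "FragmentStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- metadata ------------------------------------------------------
    @property
    def chrom_sizes(self) -> ChromSizes:
        grp = self._h5["chrom_sizes"]
        names = [n.decode() for n in grp["name"][:]]
        lengths = grp["length"][:]
        return ChromSizes(dict(zip(names, (int(x) for x in lengths))))

    @property
    def samples(self) -> list[str]:
        return sorted(self._h5["samples"])

    def barcodes(self, sample: str | None = None) -> list[str]:
        samples = [sample] if sample is not None else self.samples
        out: list[str] = []
        for s in samples:
            out.extend(b.decode() for b in self._h5[f"samples/{s}/barcodes"][:])
        return out

    def barcode_sample(self) -> dict[str, str]:
        """Map each barcode to the sample it belongs to."""
        return {b: s for s in self.samples for b in self.barcodes(s)}

    def fragment_counts(self) -> pd.Series:
        """Total fragment weight (sum of duplicate counts) per barcode."""
        totals: dict[str, float] = {}
        for sample, chrom, block in self._iter_blocks():
            bc = self._h5[f"samples/{sample}/barcodes"][:]
            w = np.bincount(block["barcode_id"], weights=block["count"], minlength=len(bc))
            for b, v in zip(bc, w):
                key = b.decode()
                totals[key] = totals.get(key, 0.0) + float(v)
        return pd.Series(totals, dtype=float).sort_index()

    # -- ingest --------------------------------------------------------
    def add_sample(self, sample_id: str, frags: pd.DataFrame) -> None:
        """Add one sample's fragments (already validated and filtered)."""
        if sample_id in self._h5["samples"]:
            raise ValueError(f"sample {sample_id!r} already present in store")
        grp = self._h5["samples"].create_group(sample_id)
        barcodes = np.array(sorted(frags["barcode"].unique()), dtype=object)
        lookup = {b: i for i, b in enumerate(barcodes)}
        grp.create_dataset("barcodes", data=np.array(barcodes, dtype="S"))
        chroms = self.chrom_sizes.names
        cg = grp.create_group("chroms")
        for chrom in chroms:
            sub = frags[frags["chrom"] == chrom]
            if len(sub) == 0:
                continue
            order = np.lexsort((sub["end"].to_numpy(), sub["start"].to_numpy()))
            sub = sub.iloc[order]
            block = cg.create_group(chrom)
            start = sub["start"].to_numpy(np.int64)
            block.create_dataset("start", data=start, compression="gzip", compression_opts=1)
            block.create_dataset(
                "length",
                data=(sub["end"].to_numpy(np.int64) - start),
                compression="gzip",
                compression_opts=1,
            )
            block.create_dataset(
                "barcode_id",
                data=np.array([lookup[b] for b in sub["barcode"]], dtype=np.int32),
                compression="gzip",
                compression_opts=1,
            )
            block.create_dataset(
                "count", data=sub["count"].to_numpy(np.int32), compression="gzip", compression_opts=1
            )
            block.attrs["max_length"] = int((sub["end"] - sub["start"]).max())

    def _iter_blocks(self) -> Iterator[tuple[str, str, dict[str, np.ndarray]]]:
        for sample in self.samples:
            cg = self._h5[f"samples/{sample}/chroms"]
            for chrom in cg:
                block = cg[chrom]
                yield sample, chrom, {
                    "start": block["start"][:],
                    "length": block["length"][:],
                    "barcode_id": block["barcode_id"][:],
                    "count": block["count"][:],
                }

    # -- queries -------------------------------------------------------
    def chrom_fragments(self, chrom: str, samples: Sequence[str] | None = None) -> pd.DataFrame:
        """All fragments on one chromosome, sorted by start."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        parts = []
        for sample in samples if samples is not None else self.samples:
            key = f"samples/{sample}/chroms/{chrom}"
            if key not in self._h5:
                continue
            block = self._h5[key]
            bc = np.array([b.decode() for b in self._h5[f"samples/{sample}/barcodes"][:]])
            start = block["start"][:]
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + block["length"][:],
                        "barcode": bc[block["barcode_id"][:]],
                        "count": block["count"][:],
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=_FRAGMENT_COLUMNS)
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["start", "end"], kind="stable").reset_index(drop=True)

    def query_fragments(
        self,
        region: str | tuple[str, int, int],
        barcodes: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        """Fragments overlapping a half-open region ``chrom:start-end``.

        Overlap means at least one shared base; a fragment whose start
        equals the region end is excluded.
        """
        chrom, qstart, qend = _parse_region(region)
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        frags = self.chrom_fragments(chrom)
        if len(frags) == 0:
            return frags
        keep = (frags["start"] < qend) & (frags["end"] > qstart)
        out = frags[keep]
        if barcodes is not None:
            out = out[out["barcode"].isin(set(barcodes))]
        return out.reset_index(drop=True)

    def global_barcode_index(self) -> dict[str, int]:
        """Barcode -> row index in the ``barcodes()`` ordering."""
        return {b: i for i, b in enumerate(self.barcodes())}

    def chrom_arrays(self, chrom: str) -> dict[str, np.ndarray]:
        """Fast path: one chromosome's fragments as parallel arrays.

        Returns start, end, count and a global integer barcode id (row in
        the ``barcodes()`` ordering), sorted by start.  Avoids string
        materialisation for large stores.
        """
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        starts, ends, bids, counts = [], [], [], []
        offset = 0
        for sample in self.samples:
            n_bc = len(self._h5[f"samples/{sample}/barcodes"])
            key = f"samples/{sample}/chroms/{chrom}"
            if key in self._h5:
                block = self._h5[key]
                s = block["start"][:]
                starts.append(s)
                ends.append(s + block["length"][:])
                bids.append(block["barcode_id"][:].astype(np.int64) + offset)
                counts.append(block["count"][:])
            offset += n_bc
        if not starts:
            z = np.array([], dtype=np.int64)
            return {"start": z, "end": z, "bid": z, "count": z}
        start = np.concatenate(starts)
        order = np.argsort(start, kind="stable")
        return {
            "start": start[order],
            "end": np.concatenate(ends)[order],
            "bid": np.concatenate(bids)[order],
            "count": np.concatenate(counts)[order].astype(np.int64),
        }

    def insertion_arrays(self, chrom: str) -> dict[str, np.ndarray]:
        """Insertion positions (start and end-1 of each fragment), sorted."""
        arr = self.chrom_arrays(chrom)
        pos = np.concatenate([arr["start"], arr["end"] - 1])
        bid = np.tile(arr["bid"], 2)
        weight = np.tile(arr["count"], 2).astype(np.float64)
        order = np.argsort(pos, kind="stable")
        return {"pos": pos[order], "bid": bid[order], "weight": weight[order]}

    # -- export --------------------------------------------------------
    def export_fragments(self, path: str | Path) -> None:
        """Write all fragments back out as a sorted fragments TSV."""
        with open(path, "w") as fh:
            for chrom in self.chrom_sizes.names:
                frags = self.chrom_fragments(chrom)
                for row in frags.itertuples(index=False):
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.barcode}\t{row.count}\n")


def _parse_region(region: str | tuple[str, int, int]) -> tuple[str, int, int]:
    if isinstance(region, tuple):
        return region
    chrom, _, span = region.partition(":")
    lo, _, hi = span.partition("-")
    return chrom, int(lo.replace(",", "")), int(hi.replace(",", ""))


def import_fragments(
    paths: Mapping[str, str | Path] | str | Path,
    out_path: str | Path,
    chrom_sizes: ChromSizes,
    min_frags: int = 0,
    sample_id: str = "sample",
    dedup: bool = False,
) -> FragmentStore:
    """Parse fragment files into a new :class:`FragmentStore`.

    Parameters
    ----------
    paths
        Either one fragment file path (imported under ``sample_id``) or a
        mapping of sample id to file path.
    min_frags
        Barcodes whose total fragment weight is below this are dropped.
    dedup
        Collapse identical (chrom, start, end, barcode) records into one
        record with summed count.

    Fragments on chromosomes absent from ``chrom_sizes``, or exceeding the
    chromosome bounds, are skipped with a logged count.  An import that
    retains no fragments raises.
    """
    if not isinstance(paths, Mapping):
        paths = {sample_id: paths}
    store = FragmentStore.create(out_path, chrom_sizes)
    total_kept = 0
    for sid, path in paths.items():
        df = read_fragments_tsv(path)
        on_contig = df["chrom"].isin(chrom_sizes.names).to_numpy()
        n_off = int((~on_contig).sum())
        df = df[on_contig]
        lengths = df["chrom"].map(chrom_sizes.sizes).to_numpy()
        in_bounds = df["end"].to_numpy() <= lengths
        n_oob = int((~in_bounds).sum())
        df = df[in_bounds]
        if n_off or n_oob:
            logger.info(
                "%s: skipped %d fragments on unlisted chromosomes, %d beyond chromosome bounds",
                sid,
                n_off,
                n_oob,
            )
        if dedup:
            df = (
                df.groupby(["chrom", "start", "end", "barcode"], as_index=False)["count"]
                .sum()
                .reindex(columns=_FRAGMENT_COLUMNS)
            )
        if min_frags > 0:
            weight = df.groupby("barcode")["count"].sum()
            keep = set(weight[weight >= min_frags].index)
            df = df[df["barcode"].isin(keep)]
        if len(df):
            store.add_sample(sid, df)
            total_kept += len(df)
    if total_kept == 0:
        store.close()
        raise FragmentFileError("import produced an empty store; check chrom sizes and min_frags")
    return store


def insertion_sites(frags: pd.DataFrame) -> pd.DataFrame:
    """Expand fragments into Tn5 insertion events.

    Each fragment [start, end) contributes two insertions, at ``start``
    and ``end - 1``, each carrying the fragment's duplicate count as
    weight; total insertion weight is exactly twice the fragment weight.
    """
    pos = np.concatenate([frags["start"].to_numpy(), frags["end"].to_numpy() - 1])
    return pd.DataFrame(
        {
            "chrom": np.tile(frags["chrom"].to_numpy(), 2),
            "pos": pos,
            "barcode": np.tile(frags["barcode"].to_numpy(), 2),
            "count": np.tile(frags["count"].to_numpy(), 2),
        }
    )
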