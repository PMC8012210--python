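"""Tn5 insertion-bias modelling and bias-adjusted TF footprints.

Tn5 inserts preferentially at certain sequences; aggregate insertion
profiles around motif sites therefore mix true TF protection with
sequence bias.  A hexamer table (observed insertion-centred k-mer
frequency over genomic background frequency) models the bias, and the
footprint normalisation divides the flank-rescaled observed profile by
the flank-rescaled bias-expected profile, so a bias-only profile comes
out flat at 1 and genuine protection shows as a central dip.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentStore

logger = logging.getLogger(__name__)


@dataclass
class KmerBiasTable:
    """Observed vs genomic k-mer frequencies at insertion centres."""

    k: int
    observed: dict[str, float]
    background: dict[str, float]
    ratio: dict[str, float]

    @classmethod
    def uniform(cls, k: int = 6) -> "KmerBiasTable":
        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
        f = 1.0 / len(kmers)
        return cls(k, {m: f for m in kmers}, {m: f for m in kmers}, {m: 1.0 for m in kmers})


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int64)
    u = np.frombuffer(seq.encode(), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        arr[u == b] = i
    return arr


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer code of the k-mer starting at each position (-1 where any N)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        codes = codes * 4 + np.clip(arr[j : n + j], 0, 3)
        bad |= arr[j : n + j] < 0
    codes[bad] = -1
    return codes


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def build_kmer_bias(store: FragmentStore, genome, k: int = 6) -> KmerBiasTable:
    """Hexamer insertion-bias table from a store and its genome sequence.

    The k-mer centred on each insertion (reference strand; insertion at
    position p reads [p - k//2, p - k//2 + k)) is tallied, weighted by
    duplicate count; the background is the genome-wide k-mer frequency.
    Insertions too close to a sequence edge are skipped with a count.
    """
    half = k // 2
    n_codes = 4**k
    obs = np.zeros(n_codes)
    bg = np.zeros(n_codes)
    n_skipped = 0
    for chrom in store.chrom_sizes.names:
        seq = str(genome[chrom][:]).upper()
        codes = _kmer_codes(_encode_seq(seq), k)
        valid = codes >= 0
        bg += np.bincount(codes[valid], minlength=n_codes)
        ins = store.insertion_arrays(chrom)
        pos, weight = ins["pos"], ins["weight"]
        ok = (pos >= half) & (pos - half < len(codes))
        n_skipped += int((~ok).sum())
        ic = codes[pos[ok] - half]
        iv = ic >= 0
        obs += np.bincount(ic[iv], weights=weight[ok][iv], minlength=n_codes)
    if n_skipped:
        logger.info("skipped %d insertions near sequence edges", n_skipped)
    obs_f = obs / obs.sum()
    bg_f = bg / bg.sum()
    present = np.flatnonzero(bg > 0)
    observed = {_code_to_kmer(int(c), k): float(obs_f[c]) for c in present if obs[c] > 0}
    background = {_code_to_kmer(int(c), k): float(bg_f[c]) for c in present}
    ratio = {m: observed.get(m, 0.0) / background[m] for m in background}
    return KmerBiasTable(k, observed, background, ratio)

@dataclass
class Footprint:
    """Aggregate profile around motif sites for one cell group."""

    group: str
    motif: str
    positions: np.ndarray  # -flank..+flank
    observed: np.ndarray
    expected: np.ndarray
    normalized: np.ndarray


def _site_profiles(
    store: FragmentStore,
    sites: pd.DataFrame,
    barcodes: list[str] | None,
    flank: int,
) -> np.ndarray:
    """Summed strand-oriented insertion weight at each offset."""
    width = 2 * flank + 1
    profile = np.zeros(width)
    index = store.global_barcode_index()
    wanted = None
    if barcodes is not None:
        wanted = np.zeros(len(index), dtype=bool)
        for b in barcodes:
            wanted[index[b]] = True
    for chrom, sub in sites.groupby("chrom"):
        ins = store.insertion_arrays(chrom)
        pos, weight, bid = ins["pos"], ins["weight"], ins["bid"]
        if wanted is not None:
            keep = wanted[bid]
            pos, weight = pos[keep], weight[keep]
        if len(pos) == 0:
            continue
        for center, strand in zip(sub["pos"].to_numpy(), sub["strand"].to_numpy()):
            lo = np.searchsorted(pos, center - flank, side="left")
            hi = np.searchsorted(pos, center + flank, side="right")
            if lo == hi:
                continue
            off = pos[lo:hi] - center
            if strand == "-":
                off = -off
            np.add.at(profile, off + flank, weight[lo:hi])
    return profile


def _site_bias_expectation(
    sites: pd.DataFrame, genome, bias: KmerBiasTable, flank: int
) -> np.ndarray:
    """Sum over sites of the bias ratio of the k-mer at each offset."""
    k, half = bias.k, bias.k // 2
    width = 2 * flank + 1
    expected = np.zeros(width)
    ratio_by_code = np.zeros(4**k)
    for mer, r in bias.ratio.items():
        code = 0
        for b in mer:
            code = code * 4 + "ACGT".index(b)
        ratio_by_code[code] = r
    for chrom, sub in sites.groupby("chrom"):
        seq = str(genome[chrom][:]).upper()
        codes = _kmer_codes(_encode_seq(seq), k)
        # per-base bias ratio, centred: position p reads k-mer starting p-half
        r = np.zeros(len(seq))
        span = slice(half, half + len(codes))
        rc = np.where(codes >= 0, ratio_by_code[np.clip(codes, 0, None)], 0.0)
        r[span] = rc
        for center, strand in zip(sub["pos"].to_numpy(), sub["strand"].to_numpy()):
            lo, hi = center - flank, center + flank + 1
            if lo < 0 or hi > len(seq):
                continue
            window = r[lo:hi]
            expected += window[::-1] if strand == "-" else window
    return expected


def footprint(
    store: FragmentStore,
    sites: pd.DataFrame,
    genome,
    bias: KmerBiasTable,
    groups: dict[str, list[str]] | None = None,
    flank: int = 250,
    edge: int = 50,
    motif_name: str = "motif",
) -> list[Footprint]:
    """Bias-adjusted aggregate footprints per cell group.

    ``sites``: chrom/pos/strand motif site table (minus-strand sites
    contribute reversed offsets).  Observed and expected profiles are each
    rescaled by their mean over the outermost ``edge`` bases per side, and
    the normalised profile is their ratio — identity adjustment under a
    uniform bias table.
    """
    if len(sites) == 0:
        raise ValueError("no motif sites given")
    if groups is None:
        groups = {"all": None}  # type: ignore[dict-item]
    expected = _site_bias_expectation(sites, genome, bias, flank)
    positions = np.arange(-flank, flank + 1)
    width = 2 * flank + 1
    edge_mask = np.zeros(width, dtype=bool)
    edge_mask[:edge] = True
    edge_mask[-edge:] = True
    out = []
    exp_edge = expected[edge_mask].mean()
    if exp_edge <= 0:
        raise ValueError("bias expectation vanishes in flank edges")
    exp_norm = expected / exp_edge
    for name, barcodes in groups.items():
        if barcodes is not None and len(barcodes) == 0:
            raise ValueError(f"group {name!r} is empty")
        observed = _site_profiles(store, sites, barcodes, flank)
        obs_edge = observed[edge_mask].mean()
        if obs_edge <= 0:
            raise ValueError(
                f"group {name!r}: no insertions in the flank edges; insufficient depth"
            )
        normalized = (observed / obs_edge) / exp_norm
        out.append(
            Footprint(name, motif_name, positions, observed, expected, normalized)
        )
    return out


def footprints_to_tsv(footprints: list[Footprint], path: str) -> None:
    rows = []
    for fp in footprints:
        rows.append(
            pd.DataFrame(
                {
                    "group": fp.group,
                    "motif": fp.motif,
                    "position": fp.positions,
                    "observed": fp.observed,
                    "expected": fp.expected,
                    "normalized": fp.normalized,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
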