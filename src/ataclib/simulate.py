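"""Ground-truthed synthetic scATAC-seq data.

The generator emits multi-sample fragment files over a small random
genome with a planted regulatory architecture: shared accessible peaks,
cell-type-specific peaks (free intergenic sites, marker-gene body sites,
and distal enhancers tied to "linked" genes), TSS-proximal signal that
produces realistic TSS enrichment, uniform background, optional
heterotypic doublets, optional hexamer insertion bias, optional
footprint-style protection at motif sites, and an optional lineage mode
that places cells on a latent pseudotime with stage-wise peak activity
ramps.  Matched expression counts can be generated with configurable
coupling to gene-body accessibility.  Everything is seeded and the truth
(type labels, doublet parents, planted peaks and links, latent time) is
returned alongside the files, so downstream recovery — clustering,
doublet detection, marker testing, link and pseudotime recovery — can be
scored exactly.

Per-cell fragment counts follow truncated normal tiers; the quality
tiers used throughout are low (1,000 +/- 500), medium (5,000 +/- 1,000)
and high (10,000 +/- 2,500) fragments per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: (mean, sd) fragments per cell for the three standard quality tiers.
QUALITY_TIERS = {"low": (1000, 500), "medium": (5000, 1000), "high": (10000, 2500)}


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_cell_types: int = 3
    cells_per_type: int = 500
    n_samples: int = 2
    frags_per_cell: tuple[float, float] = QUALITY_TIERS["high"]
    min_frags_per_cell: int = 100
    doublet_fraction: float = 0.0
    doublet_depth_factor: float = 1.25
    genes_per_chrom: int = 30
    shared_peaks_per_chrom: int = 20
    free_specific_per_chrom_per_type: int = 9
    marker_genes_per_type: int = 6
    linked_genes_per_type: int = 5
    peak_width: int = 501
    tss_fraction: float = 0.10
    peak_fraction: float = 0.45
    specific_peak_weight: float = 1.5
    specific_leak: float = 0.0
    margin: int = 10_000
    kmer_bias: tuple[str, float] | None = None  # (hexamer, target observed/background ratio)
    protect_sites: bool = False  # carve a protected footprint at type-0 body/free sites
    protect_halfwidth: int = 10
    plant_consensus: str | None = None  # sequence written at type-0 specific peak centres
    lineage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.doublet_fraction <= 1):
            raise ValueError("doublet_fraction must be in [0, 1]")
        if self.tss_fraction + self.peak_fraction > 1:
            raise ValueError("component fractions exceed 1")
        per_type_peaks = self.marker_genes_per_type + self.linked_genes_per_type
        if per_type_peaks * self.n_cell_types > self.genes_per_chrom * self.n_chroms:
            raise ValueError("more marker/linked genes than genes in the genome")


@dataclass
class SimResult:
    config: SimConfig
    out_dir: Path
    fragment_files: dict[str, Path]
    genome_fasta: Path
    gene_bed: Path
    chrom_sizes_file: Path
    truth: pd.DataFrame  # per barcode: sample, cell_type, is_doublet, parents, latent_time
    genes: pd.DataFrame  # chrom/start/end/name/strand/gene_class/class_type
    peaks: pd.DataFrame  # chrom/start/end/center/kind/cell_type/role/gene
    chrom_names: list[str]

    @property
    def linked_pairs(self) -> pd.DataFrame:
        enh = self.peaks[self.peaks["role"] == "enhancer"]
        return enh[["chrom", "center", "cell_type", "gene"]].reset_index(drop=True)


def _layout(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes and peaks on a fixed pitch so nothing collides."""
    genes_rows = []
    peak_rows = []
    n_types = config.n_cell_types
    half = (config.peak_width - 1) // 2
    gene_i = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_slots = (
            config.genes_per_chrom
            + config.shared_peaks_per_chrom
            + config.free_specific_per_chrom_per_type * n_types
        )
        pitch = (config.chrom_length - 2 * config.margin) // n_slots
        slot_kinds = (
            ["gene"] * config.genes_per_chrom
            + ["shared"] * config.shared_peaks_per_chrom
            + sum([[f"specific{t}"] * config.free_specific_per_chrom_per_type for t in range(n_types)], [])
        )
        order = rng.permutation(len(slot_kinds))
        for s, oi in enumerate(order):
            kind = slot_kinds[oi]
            slot_start = config.margin + s * pitch
            if kind == "gene":
                length = int(rng.integers(6000, 9000))
                start = slot_start + 2000
                strand = "+" if gene_i % 2 == 0 else "-"
                genes_rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + length,
                        "name": f"gene{gene_i}",
                        "strand": strand,
                        "gene_class": "neutral",
                        "class_type": -1,
                    }
                )
                gene_i += 1
            else:
                center = slot_start + pitch // 2
                ctype = -1 if kind == "shared" else int(kind.replace("specific", ""))
                peak_rows.append(
                    {
                        "chrom": chrom,
                        "start": center - half,
                        "end": center + half + 1,
                        "center": center,
                        "kind": "shared" if ctype < 0 else "specific",
                        "cell_type": ctype,
                        "role": "free",
                        "gene": "",
                    }
                )
    genes = pd.DataFrame(genes_rows)
    peaks = pd.DataFrame(peak_rows)

    # assign marker (body peak) and linked (enhancer peak) genes per type
    neutral = list(genes.index)
    rng.shuffle(neutral)
    ptr = 0
    for t in range(n_types):
        for _ in range(config.marker_genes_per_type):
            gi = neutral[ptr]
            ptr += 1
            genes.loc[gi, ["gene_class", "class_type"]] = ["marker", t]
            g = genes.loc[gi]
            center = int(g["start"] + 0.6 * (g["end"] - g["start"]))
            peaks.loc[len(peaks)] = {
                "chrom": g["chrom"],
                "start": center - half,
                "end": center + half + 1,
                "center": center,
                "kind": "specific",
                "cell_type": t,
                "role": "body",
                "gene": g["name"],
            }
        for _ in range(config.linked_genes_per_type):
            gi = neutral[ptr]
            ptr += 1
            genes.loc[gi, ["gene_class", "class_type"]] = ["linked", t]
            g = genes.loc[gi]
            # distal enhancer downstream of the gene body, well outside promoters
            center = int(g["end"] + 4000) if g["strand"] == "+" else int(g["start"] - 4000)
            peaks.loc[len(peaks)] = {
                "chrom": g["chrom"],
                "start": center - half,
                "end": center + half + 1,
                "center": center,
                "kind": "specific",
                "cell_type": t,
                "role": "enhancer",
                "gene": g["name"],
            }
    return genes, peaks


def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Nucleosome-free (50-120 bp) / mono-nucleosome (180-250 bp) mixture."""
    nfr = rng.random(n) < 0.65
    out = np.where(
        nfr,
        rng.integers(50, 121, size=n),
        rng.integers(180, 251, size=n),
    )
    return out.astype(np.int64)


def _stage_weights(u: np.ndarray, stage: int, n_stages: int) -> np.ndarray:
    """Triangular activity ramp of stage ``stage`` at latent time u."""
    centers = np.linspace(0, 1, n_stages)
    width = 1.0 / (n_stages - 1) * 1.5
    return np.maximum(1 - np.abs(u - centers[stage]) / width, 0.0) + 0.05


class _FragmentSampler:
    """Draws fragments for cells of a given type (or latent time)."""

    def __init__(self, config: SimConfig, genes: pd.DataFrame, peaks: pd.DataFrame):
        self.config = config
        self.genes = genes
        self.peaks = peaks
        plus = genes["strand"].to_numpy() != "-"
        self.tss_chrom = genes["chrom"].to_numpy()
        self.tss_pos = np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)
        self.chrom_of_peak = peaks["chrom"].to_numpy()
        self.center_of_peak = peaks["center"].to_numpy()
        self.shared_idx = np.flatnonzero(peaks["kind"].to_numpy() == "shared")
        self.specific_idx = {
            t: np.flatnonzero(peaks["cell_type"].to_numpy() == t)
            for t in range(config.n_cell_types)
        }
        self.protected = np.zeros(len(peaks), dtype=bool)
        if config.protect_sites:
            self.protected = (
                (peaks["cell_type"].to_numpy() == 0) & (peaks["role"].to_numpy() != "enhancer")
            )

    def peak_probabilities(self, cell_type: int, u: float | None) -> np.ndarray:
        cfg = self.config
        w = np.zeros(len(self.peaks))
        w[self.shared_idx] = 1.0
        if u is None:
            for t in range(cfg.n_cell_types):
                val = cfg.specific_peak_weight if t == cell_type else cfg.specific_leak
                w[self.specific_idx[t]] = val
        else:
            for t in range(cfg.n_cell_types):
                w[self.specific_idx[t]] = cfg.specific_peak_weight * _stage_weights(
                    np.array([u]), t, cfg.n_cell_types
                )[0]
        return w / w.sum()

    def draw(
        self, n: int, cell_type: int, rng: np.random.Generator, u: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (chrom index array, start, end) for n fragments."""
        cfg = self.config
        comp = rng.random(n)
        n_tss = int((comp < cfg.tss_fraction).sum())
        n_peak = int(((comp >= cfg.tss_fraction) & (comp < cfg.tss_fraction + cfg.peak_fraction)).sum())
        n_bg = n - n_tss - n_peak
        chroms, mids, lengths = [], [], []
        if n_tss:
            pick = rng.integers(0, len(self.tss_pos), size=n_tss)
            mids.append(self.tss_pos[pick] + rng.normal(0, 30, size=n_tss))
            chroms.append(self.tss_chrom[pick])
            lengths.append(rng.integers(50, 121, size=n_tss).astype(np.int64))
        if n_peak:
            probs = self.peak_probabilities(cell_type, u)
            pick = rng.choice(len(probs), size=n_peak, p=probs)
            mid = self.center_of_peak[pick] + rng.normal(0, 80, size=n_peak)
            length = _draw_lengths(rng, n_peak)
            if cfg.protect_sites:
                prot = self.protected[pick]
                if prot.any():
                    mid[prot], length[prot] = self._protected_positions(
                        self.center_of_peak[pick[prot]], rng
                    )
            mids.append(mid)
            chroms.append(self.chrom_of_peak[pick])
            lengths.append(length)
        if n_bg:
            ci = rng.integers(0, cfg.n_chroms, size=n_bg)
            chroms.append(np.array([f"chr{c + 1}" for c in range(cfg.n_chroms)])[ci])
            mids.append(rng.uniform(cfg.margin, cfg.chrom_length - cfg.margin, size=n_bg))
            lengths.append(_draw_lengths(rng, n_bg))
        chrom = np.concatenate(chroms)
        mid = np.concatenate(mids)
        length = np.concatenate(lengths)
        start = np.clip((mid - length / 2).astype(np.int64), 0, cfg.chrom_length - 2)
        end = np.clip(start + length, start + 1, cfg.chrom_length)
        return chrom, start, end

    def _protected_positions(
        self, centers: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fragment coordinates whose insertions avoid the protected core."""
        hw = self.config.protect_halfwidth
        n = len(centers)
        mid = centers + rng.normal(0, 80, size=n)
        length = _draw_lengths(rng, n)
        for _ in range(25):
            s = (mid - length / 2).astype(np.int64)
            e = s + length
            bad = (np.abs(s - centers) <= hw) | (np.abs(e - 1 - centers) <= hw)
            if not bad.any():
                break
            k = int(bad.sum())
            mid[bad] = centers[bad] + rng.normal(0, 80, size=k)
            length[bad] = _draw_lengths(rng, k)
        return mid, length


def _apply_kmer_bias(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    kmer_positions: dict[str, np.ndarray],
    target_ratio: float,
    kmer_genome_freq: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Relocate a fraction of fragment starts onto preferred-kmer sites.

    The relocation fraction is chosen so the observed frequency of the
    preferred k-mer at insertion centres is ``target_ratio`` times its
    genomic frequency (only fragment starts are relocated; ends stay
    random, hence the factor 2).
    """
    q = kmer_genome_freq
    phi = min(2 * q * (target_ratio - 1) / max(1 - q, 1e-12), 1.0)
    move = rng.random(len(start)) < phi
    length = end - start
    for ch, pos_arr in kmer_positions.items():
        sel = move & (chrom == ch)
        k = int(sel.sum())
        if k == 0 or len(pos_arr) == 0:
            continue
        new_start = pos_arr[rng.integers(0, len(pos_arr), size=k)]
        start = start.copy()
        start[sel] = new_start
        end = end.copy()
        end[sel] = new_start + length[sel]
    return start, end


def _random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        f"chr{c + 1}": rng.integers(0, 4, size=config.chrom_length).astype(np.int8)
        for c in range(config.n_chroms)
    }


def _genome_to_fasta(genome: dict[str, np.ndarray], path: Path) -> None:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            seq = lut[arr].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate fragment files, genome, annotation and truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes, peaks = _layout(config, rng)
    genome = _random_genome(config, rng)

    if config.plant_consensus:
        cons = np.array(
            [b"ACGT".index(b.encode()) for b in config.plant_consensus], dtype=np.int8
        )
        for row in peaks[(peaks["cell_type"] == 0) & (peaks["kind"] == "specific")].itertuples():
            arr = genome[row.chrom]
            c = row.center - len(cons) // 2
            arr[c : c + len(cons)] = cons

    kmer_positions: dict[str, np.ndarray] = {}
    kmer_freq = 0.0
    if config.kmer_bias is not None:
        kmer, _ratio = config.kmer_bias
        enc = np.array([b"ACGT".index(b.encode()) for b in kmer], dtype=np.int8)
        total_sites = 0
        total_len = 0
        half = len(kmer) // 2
        for chrom, arr in genome.items():
            n = len(arr) - len(enc) + 1
            match = np.ones(n, dtype=bool)
            for j, b in enumerate(enc):
                match &= arr[j : n + j] == b
            # store the *insertion centre* position for each occurrence
            kmer_positions[chrom] = np.flatnonzero(match) + half
            total_sites += len(kmer_positions[chrom])
            total_len += n
        kmer_freq = total_sites / total_len

    sampler = _FragmentSampler(config, genes, peaks)
    n_types = config.n_cell_types
    n_singlets = n_types * config.cells_per_type
    n_doublets = int(round(config.doublet_fraction * n_singlets / max(1 - config.doublet_fraction, 1e-9)))

    mean, sd = config.frags_per_cell
    truth_rows = []
    frag_parts: dict[str, list[pd.DataFrame]] = {f"s{j + 1}": [] for j in range(config.n_samples)}

    def emit(barcode: str, sample: str, chrom, start, end) -> None:
        frag_parts[sample].append(
            pd.DataFrame({"chrom": chrom, "start": start, "end": end, "barcode": barcode, "count": 1})
        )

    singlet_types = np.repeat(np.arange(n_types), config.cells_per_type)
    latent = rng.random(n_singlets) if config.lineage else np.full(n_singlets, np.nan)
    if config.lineage:
        singlet_types = np.minimum((latent * n_types).astype(int), n_types - 1)
    for i in range(n_singlets):
        t = int(singlet_types[i])
        sample = f"s{i % config.n_samples + 1}"
        barcode = f"{sample}#BC{i:05d}"
        n = max(int(round(rng.normal(mean, sd))), config.min_frags_per_cell)
        u = float(latent[i]) if config.lineage else None
        chrom, start, end = sampler.draw(n, t, rng, u=u)
        if config.kmer_bias is not None:
            start, end = _apply_kmer_bias(
                chrom, start, end, kmer_positions, config.kmer_bias[1], kmer_freq, rng
            )
        emit(barcode, sample, chrom, start, end)
        truth_rows.append(
            {
                "barcode": barcode,
                "sample": sample,
                "cell_type": t,
                "is_doublet": False,
                "parent_a": "",
                "parent_b": "",
                "latent_time": latent[i],
                "n_frags_drawn": n,
            }
        )

    for d in range(n_doublets):
        ta, tb = rng.choice(n_types, size=2, replace=False)
        pa = int(rng.integers(0, n_singlets))
        pb = int(rng.integers(0, n_singlets))
        sample = f"s{d % config.n_samples + 1}"
        barcode = f"{sample}#DB{d:05d}"
        n = max(
            int(round(config.doublet_depth_factor * rng.normal(mean, sd))),
            config.min_frags_per_cell,
        )
        na = n // 2
        ca, sa, ea = sampler.draw(na, int(ta), rng)
        cb, sb, eb = sampler.draw(n - na, int(tb), rng)
        emit(barcode, sample, np.concatenate([ca, cb]), np.concatenate([sa, sb]), np.concatenate([ea, eb]))
        truth_rows.append(
            {
                "barcode": barcode,
                "sample": sample,
                "cell_type": -1,
                "is_doublet": True,
                "parent_a": f"type{ta}:{pa}",
                "parent_b": f"type{tb}:{pb}",
                "latent_time": np.nan,
                "n_frags_drawn": n,
            }
        )

    fragment_files = {}
    for sample, parts in frag_parts.items():
        df = pd.concat(parts, ignore_index=True)
        path = out_dir / f"fragments_{sample}.tsv"
        df.to_csv(path, sep="\t", header=False, index=False)
        fragment_files[sample] = path

    fasta = out_dir / "genome.fa"
    _genome_to_fasta(genome, fasta)
    sizes = out_dir / "genome.chrom.sizes"
    with open(sizes, "w") as fh:
        for c in range(config.n_chroms):
            fh.write(f"chr{c + 1}\t{config.chrom_length}\n")
    gene_bed = out_dir / "genes.bed"
    with open(gene_bed, "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    peaks.to_csv(out_dir / "planted_peaks.tsv", sep="\t", index=False)

    return SimResult(
        config=config,
        out_dir=out_dir,
        fragment_files=fragment_files,
        genome_fasta=fasta,
        gene_bed=gene_bed,
        chrom_sizes_file=sizes,
        truth=truth,
        genes=genes,
        peaks=peaks,
        chrom_names=[f"chr{c + 1}" for c in range(config.n_chroms)],
    )


def simulate_paired_expression(
    sim: SimResult,
    coupling: float = 1.0,
    effect_size: float = 5.0,
    base_rate: float = 5.0,
    seed: int = 0,
):
    """Matched cell x gene expression counts.

    Marker and linked genes are expressed ``effect_size`` times higher in
    their planted cell type, scaled by ``coupling`` (0 = expression
    independent of accessibility truth); all genes get a lognormal base
    rate and per-cell depth factor; counts are Poisson.  Doublets mix
    their two parent types' rates.
    """
    from .features import FeatureMatrix, FeatureSet

    rng = np.random.default_rng(seed)
    genes = sim.genes
    truth = sim.truth
    n_cells = len(truth)
    n_genes = len(genes)
    base = base_rate * rng.lognormal(0, 0.4, size=n_genes)
    mult = np.ones((sim.config.n_cell_types, n_genes))
    for j, g in enumerate(genes.itertuples(index=False)):
        if g.gene_class in ("marker", "linked"):
            t = int(g.class_type)
            mult[t, j] = 1.0 + coupling * (effect_size - 1.0)
    depth_factor = rng.lognormal(0, 0.3, size=n_cells)
    rates = np.empty((n_cells, n_genes))
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.is_doublet:
            ta = int(row.parent_a.split(":")[0].replace("type", ""))
            tb = int(row.parent_b.split(":")[0].replace("type", ""))
            m = (mult[ta] + mult[tb]) / 2
        else:
            m = mult[int(row.cell_type)]
        rates[i] = base * m * depth_factor[i]
    counts = rng.poisson(rates)
    feats = FeatureSet(genes[["chrom", "start", "end", "name"]].copy(), kind="gene")
    return FeatureMatrix(list(truth["barcode"]), feats, sp.csr_matrix(counts))
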