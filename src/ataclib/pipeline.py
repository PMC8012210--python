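"""End-to-end workflow orchestration with provenance and resumability.

Stages: import -> qc -> tiles -> lsi (with doublet removal) -> cluster ->
peaks -> peak_matrix -> markers.  Each stage writes its standard-format
output plus a JSON provenance record (parameters, seed, input hashes);
a rerun skips a stage whose provenance matches unless forced, and
changing a stage's parameters invalidates that stage and everything
downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

STAGE_ORDER = ["import", "qc", "tiles", "lsi", "cluster", "peaks", "peak_matrix", "markers"]


@dataclass
class PipelineConfig:
    fragments: dict[str, str]  # sample -> fragments TSV
    chrom_sizes: str
    tss_bed: str
    out_dir: str
    seed: int = 0
    min_frags_import: int = 100
    min_tss: float = 4.0
    min_frags: float = 1000
    tile_size: int = 500
    doublet_filter_ratio: float = 1.0
    doublet_k: int = 10
    lsi_iterations: int = 2
    n_components: int = 30
    n_var_features: int = 25_000
    cluster_resolution: float = 0.8
    k_neighbors: int = 30
    peak_width: int = 501
    min_rep_support: int = 2
    pseudobulk_min_cells: int = 40
    pseudobulk_max_cells: int = 500
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage_params(config: PipelineConfig, stage: str) -> dict[str, Any]:
    fields = {
        "import": ["min_frags_import"],
        "qc": ["min_tss", "min_frags"],
        "tiles": ["tile_size"],
        "lsi": ["doublet_filter_ratio", "doublet_k", "lsi_iterations", "n_components",
                 "n_var_features", "cluster_resolution", "k_neighbors", "seed"],
        "cluster": ["cluster_resolution", "k_neighbors", "seed"],
        "peaks": ["peak_width", "min_rep_support", "pseudobulk_min_cells",
                   "pseudobulk_max_cells", "seed"],
        "peak_matrix": [],
        "markers": ["seed"],
    }
    return {f: getattr(config, f) for f in fields[stage]}


class Pipeline:
    def __init__(self, config: PipelineConfig, force: bool = False):
        self.config = config
        self.force = force
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._provenance_chain: str = ""

    # -- provenance helpers -------------------------------------------
    def _prov_path(self, stage: str) -> Path:
        return self.out / f"{stage}.provenance.json"

    def _record(self, stage: str, inputs: list[str]) -> dict:
        rec = {
            "stage": stage,
            "params": _stage_params(self.config, stage),
            "inputs": {str(p): _hash_file(p) for p in inputs if Path(p).exists()},
            "upstream": self._provenance_chain,
        }
        return rec

    def _up_to_date(self, stage: str, rec: dict, outputs: list[Path]) -> bool:
        if self.force:
            return False
        path = self._prov_path(stage)
        if not path.exists() or not all(o.exists() for o in outputs):
            return False
        old = json.loads(path.read_text())
        return {k: old.get(k) for k in ("stage", "params", "inputs", "upstream")} == rec

    def _commit(self, stage: str, rec: dict) -> None:
        self._prov_path(stage).write_text(json.dumps(rec, indent=1, default=str))
        self._provenance_chain = hashlib.sha256(
            (self._provenance_chain + json.dumps(rec, sort_keys=True, default=str)).encode()
        ).hexdigest()[:16]

    def _chain_from(self, stage: str) -> None:
        rec = json.loads(self._prov_path(stage).read_text())
        self._provenance_chain = hashlib.sha256(
            (rec["upstream"] + json.dumps(rec, sort_keys=True, default=str)).encode()
        ).hexdigest()[:16]

    # -- stages --------------------------------------------------------
    def run(self) -> Path:
        from . import diff, doublets, features, fragments, lsi, peaks, qc

        cfg = self.config
        chrom_sizes = fragments.ChromSizes.from_tsv(cfg.chrom_sizes)
        store_path = self.out / "store.h5"
        stage_failed = None
        try:
            # import ----------------------------------------------------
            rec = self._record("import", list(cfg.fragments.values()) + [cfg.chrom_sizes])
            if self._up_to_date("import", rec, [store_path]):
                logger.info("stage import up to date; skipping")
            else:
                stage_failed = "import"
                store = fragments.import_fragments(
                    {s: p for s, p in cfg.fragments.items()},
                    store_path,
                    chrom_sizes,
                    min_frags=cfg.min_frags_import,
                )
                store.close()
            self._commit("import", rec)

            # qc --------------------------------------------------------
            qc_path = self.out / "cell_qc.tsv"
            rec = self._record("qc", [store_path, cfg.tss_bed])
            if self._up_to_date("qc", rec, [qc_path]):
                logger.info("stage qc up to date; skipping")
            else:
                stage_failed = "qc"
                with fragments.FragmentStore(store_path) as store:
                    tss = qc.read_tss_bed(cfg.tss_bed)
                    table = qc.compute_cell_qc(store, tss)
                    table = qc.filter_cells(table, cfg.min_tss, cfg.min_frags)
                    table.to_csv(qc_path, sep="\t", index=False)
                    qc.fragment_size_histogram(store).to_csv(
                        self.out / "fragment_sizes.tsv", sep="\t", index=False
                    )
            self._commit("qc", rec)

            # tiles -----------------------------------------------------
            tiles_path = self.out / "tiles.npz"
            rec = self._record("tiles", [store_path, str(qc_path)])
            if self._up_to_date("tiles", rec, [tiles_path]):
                logger.info("stage tiles up to date; skipping")
            else:
                stage_failed = "tiles"
                with fragments.FragmentStore(store_path) as store:
                    tm = features.build_tile_matrix(store, cfg.tile_size)
                table = pd.read_csv(qc_path, sep="\t")
                keep = table[table["pass_qc"]]["barcode"].tolist()
                tm = tm.subset_cells(keep)
                sp.save_npz(tiles_path, tm.counts)
                pd.Series(tm.barcodes).to_csv(
                    self.out / "tiles.barcodes.tsv", index=False, header=False
                )
            self._commit("tiles", rec)

            # lsi (+doublet removal) ------------------------------------
            emb_path = self.out / "embedding.tsv"
            rec = self._record("lsi", [str(tiles_path)])
            if self._up_to_date("lsi", rec, [emb_path]):
                logger.info("stage lsi up to date; skipping")
            else:
                stage_failed = "lsi"
                X = sp.load_npz(tiles_path)
                barcodes = pd.read_csv(
                    self.out / "tiles.barcodes.tsv", header=None
                )[0].tolist()
                model = lsi.IterativeLSI(
                    n_iterations=cfg.lsi_iterations,
                    n_components=min(cfg.n_components, min(X.shape) - 1),
                    n_var_features=cfg.n_var_features,
                    cluster_resolution=cfg.cluster_resolution,
                    k_neighbors=cfg.k_neighbors,
                    random_state=cfg.seed,
                ).fit(X)
                det = doublets.SyntheticDoubletDetector(
                    k=cfg.doublet_k,
                    filter_ratio=cfg.doublet_filter_ratio,
                    random_state=cfg.seed,
                ).fit(X, model)
                removed = det.predict()
                scores = det.scores_.copy()
                scores.insert(0, "barcode", barcodes)
                scores.to_csv(self.out / "doublet_scores.tsv", sep="\t", index=False)
                keep_idx = np.flatnonzero(~removed)
                if len(keep_idx) < len(barcodes):
                    model = lsi.IterativeLSI(
                        n_iterations=cfg.lsi_iterations,
                        n_components=min(cfg.n_components, len(keep_idx) - 1),
                        n_var_features=cfg.n_var_features,
                        cluster_resolution=cfg.cluster_resolution,
                        k_neighbors=cfg.k_neighbors,
                        random_state=cfg.seed,
                    ).fit(X[keep_idx])
                emb = pd.DataFrame(model.embedding_)
                emb.insert(0, "barcode", [barcodes[i] for i in keep_idx])
                emb.to_csv(emb_path, sep="\t", index=False, float_format="%.6g")
            self._commit("lsi", rec)

            # cluster ---------------------------------------------------
            clust_path = self.out / "clusters.tsv"
            rec = self._record("cluster", [str(emb_path)])
            if self._up_to_date("cluster", rec, [clust_path]):
                logger.info("stage cluster up to date; skipping")
            else:
                stage_failed = "cluster"
                emb = pd.read_csv(emb_path, sep="\t")
                coords = emb.drop(columns="barcode").to_numpy()
                labels = lsi.cluster_cells(
                    coords, cfg.k_neighbors, cfg.cluster_resolution, cfg.seed
                )
                pd.DataFrame({"barcode": emb["barcode"], "cluster": labels}).to_csv(
                    clust_path, sep="\t", index=False
                )
            self._commit("cluster", rec)

            # peaks -----------------------------------------------------
            peaks_path = self.out / "peaks.tsv"
            rec = self._record("peaks", [str(clust_path), store_path])
            if self._up_to_date("peaks", rec, [peaks_path]):
                logger.info("stage peaks up to date; skipping")
            else:
                stage_failed = "peaks"
                clusters = pd.read_csv(clust_path, sep="\t")
                qc_table = pd.read_csv(qc_path, sep="\t")
                cells = clusters.merge(qc_table[["barcode", "sample"]], on="barcode")
                plan = peaks.make_pseudobulk_plan(
                    cells,
                    min_cells=cfg.pseudobulk_min_cells,
                    max_cells=cfg.pseudobulk_max_cells,
                    seed=cfg.seed,
                )
                with fragments.FragmentStore(store_path) as store:
                    peak_set = peaks.call_peaks_from_plan(
                        store,
                        plan,
                        width=cfg.peak_width,
                        min_rep_support=cfg.min_rep_support,
                    )
                peak_set.to_csv(peaks_path, sep="\t", index=False)
            self._commit("peaks", rec)

            # peak matrix -----------------------------------------------
            pm_path = self.out / "peak_matrix.npz"
            rec = self._record("peak_matrix", [str(peaks_path), store_path])
            if self._up_to_date("peak_matrix", rec, [pm_path]):
                logger.info("stage peak_matrix up to date; skipping")
            else:
                stage_failed = "peak_matrix"
                peak_set = pd.read_csv(peaks_path, sep="\t")
                with fragments.FragmentStore(store_path) as store:
                    pm = features.build_peak_matrix(store, peak_set)
                clusters = pd.read_csv(clust_path, sep="\t")
                pm = pm.subset_cells(clusters["barcode"].tolist())
                sp.save_npz(pm_path, pm.counts)
                pm.features.intervals.to_csv(
                    self.out / "peak_matrix.features.tsv", sep="\t", index=False
                )
            self._commit("peak_matrix", rec)

            # markers ---------------------------------------------------
            markers_path = self.out / "markers.tsv"
            rec = self._record("markers", [str(pm_path), str(clust_path)])
            if self._up_to_date("markers", rec, [markers_path]):
                logger.info("stage markers up to date; skipping")
            else:
                stage_failed = "markers"
                X = sp.load_npz(pm_path)
                clusters = pd.read_csv(clust_path, sep="\t")
                qc_table = pd.read_csv(qc_path, sep="\t").set_index("barcode")
                qc_table = qc_table.loc[clusters["barcode"]]
                bias = np.column_stack(
                    [np.log10(qc_table["n_frags"] + 1), qc_table["tss_enrichment"]]
                )
                feat_names = pd.read_csv(
                    self.out / "peak_matrix.features.tsv", sep="\t"
                )["name"].tolist()
                res = diff.markers_per_cluster(
                    X, clusters["cluster"].to_numpy(), bias, seed=self.config.seed
                )
                res["feature"] = [feat_names[i] if isinstance(i, (int, np.integer)) else i
                                   for i in res["feature"]]
                res.to_csv(markers_path, sep="\t", index=False, float_format="%.6g")
            self._commit("markers", rec)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage_failed!r} failed: {exc}") from exc
        return self.out


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    return Pipeline(config, force=force).run()
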