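"""Shared fixtures: small seeded synthetic datasets reused across tests.

Everything is generated at test time by the package's own simulator; no
data files ship with the repository.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ataclib.features import build_tile_matrix
from ataclib.fragments import ChromSizes, import_fragments
from ataclib.lsi import IterativeLSI
from ataclib.simulate import SimConfig, simulate


def small_config(**overrides) -> SimConfig:
    """Three cell types, medium-small depth, a 2 x 0.5 Mb genome."""
    params = dict(
        chrom_length=500_000,
        cells_per_type=150,
        frags_per_cell=(3000, 600),
        genes_per_chrom=10,
        shared_peaks_per_chrom=8,
        free_specific_per_chrom_per_type=4,
        marker_genes_per_type=3,
        linked_genes_per_type=2,
        seed=7,
    )
    params.update(overrides)
    return SimConfig(**params)


class Dataset:
    """Bundle of simulated data plus imported store and tile matrix."""

    def __init__(self, sim, store, tile_matrix):
        self.sim = sim
        self.store = store
        self.tiles = tile_matrix
        self.truth = sim.truth.set_index("barcode").loc[tile_matrix.barcodes]

    @property
    def chrom_sizes(self) -> ChromSizes:
        return self.store.chrom_sizes


def make_dataset(tmp_dir, config: SimConfig) -> Dataset:
    sim = simulate(config, tmp_dir)
    sizes = ChromSizes.from_tsv(sim.chrom_sizes_file)
    store = import_fragments(
        dict(sim.fragment_files), tmp_dir / "store.h5", sizes, min_frags=100
    )
    tiles = build_tile_matrix(store)
    return Dataset(sim, store, tiles)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory) -> Dataset:
    """Clean 3-type dataset (no doublets)."""
    return make_dataset(tmp_path_factory.mktemp("sim_clean"), small_config())


@pytest.fixture(scope="session")
def lsi_model(dataset) -> IterativeLSI:
    return IterativeLSI(
        n_components=15, n_top_features=5000, n_var_features=5000, random_state=7
    ).fit(dataset.tiles.counts)


@pytest.fixture(scope="session")
def doublet_dataset(tmp_path_factory) -> Dataset:
    """Same conditions plus 8% planted heterotypic doublets."""
    return make_dataset(
        tmp_path_factory.mktemp("sim_doublet"), small_config(doublet_fraction=0.08, seed=8)
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


# -- tiny hand-built fragment stores --------------------------------------

@pytest.fixture()
def toy_store(tmp_path):
    """Store builder: pass a fragment DataFrame and chrom sizes."""

    counter = iter(range(1000))

    def build(frags: pd.DataFrame, sizes: dict[str, int], min_frags: int = 0):
        i = next(counter)
        path = tmp_path / f"frags{i}.tsv"
        frags.to_csv(path, sep="\t", header=False, index=False)
        return import_fragments(
            path, tmp_path / f"toy{i}.h5", ChromSizes(sizes), min_frags=min_frags
        )

    return build
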