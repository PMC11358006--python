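import numpy as np
import pandas as pd
import pytest

from ersecretome.io import PhosphoSiteTable
from ersecretome.simulate import (
    default_design,
    simulate_phospho,
    simulate_proteins,
    simulate_sc_counts,
)


@pytest.fixture(scope="session")
def sc_small():
    """A small cell-by-gene simulation with planted subpopulation truth."""
    adata, truth = simulate_sc_counts(
        n_cells=800, n_genes=300, enriched_gene_count=30, seed=11
    )
    return adata, truth


@pytest.fixture(scope="session")
def protein_set():
    records, truth = simulate_proteins(60, 60, 30, ers_fraction=0.2, seed=5)
    return records, truth


@pytest.fixture(scope="session")
def phospho_sim():
    table, truth = simulate_phospho(n_sites=300, seed=7)
    return table, truth


def make_phospho_table(intensity: np.ndarray, loc_prob=0.9, design=None) -> PhosphoSiteTable:
    """Wrap a raw site x sample log2 array into a PhosphoSiteTable."""
    n = intensity.shape[0]
    if design is None:
        design = default_design()
    assert intensity.shape[1] == len(design)
    sites = pd.DataFrame(
        {
            "protein_id": "P0",
            "residue": "S",
            "position": np.arange(1, n + 1),
            "loc_prob": loc_prob,
            "flank": "AAAAAAASAAAAAAA",
        },
        index=pd.Index([f"s{i:04d}" for i in range(n)], name="site_id"),
    )
    return PhosphoSiteTable(
        sites, pd.DataFrame(intensity, index=sites.index, columns=design.index), design
    )
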