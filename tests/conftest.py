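import numpy as np
import pandas as pd
import pytest

from gcatlas import io as gio
from gcatlas import synthetic


@pytest.fixture(scope="session")
def marker_table():
    return gio.read_marker_table(gio.packaged_data("markers.tsv"))


@pytest.fixture(scope="session")
def small_universe():
    return synthetic.default_universe(n_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_programs(small_universe, marker_table):
    return synthetic.default_programs(small_universe, marker_table, seed=11)


def three_type_config(seed=11, n=50, violations=None, n_genes=600):
    feats = synthetic.default_universe(n_genes=n_genes, seed=seed)
    table = gio.read_marker_table(gio.packaged_data("markers.tsv"))
    progs = synthetic.default_programs(feats, table, seed=seed)
    return synthetic.SimConfig(
        features=feats,
        programs=progs,
        n_cells_per_type={"GMC": n, "tumor": n, "immune": n},
        marker_assignments=table,
        qc_violations=violations or {},
        seed=seed,
    )


@pytest.fixture(scope="session")
def three_type_sim():
    cfg = three_type_config()
    adata, truth = synthetic.simulate_cells(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def lineage_sim(marker_table):
    """A 300-cell GMC -> MSC -> tumor lineage with known latent time."""
    feats = synthetic.default_universe(n_genes=600, seed=21)
    progs = synthetic.default_programs(feats, marker_table, seed=21)
    cfg = synthetic.SimConfig(
        features=feats, programs=progs, n_cells_per_type={"GMC": 1},
        marker_assignments=marker_table,
        lineage=[("GMC", 0.0), ("MSC", 0.5), ("tumor", 1.0)],
        n_lineage_cells=300, seed=21,
    )
    adata, truth = synthetic.simulate_cells(cfg)
    return cfg, adata, truth


def brute_force_qc(counts_dense: np.ndarray, special_mask: np.ndarray) -> pd.DataFrame:
    """Independent dense re-evaluation of the four QC rules, cell by cell."""
    rows = []
    for i in range(counts_dense.shape[0]):
        x = counts_dense[i].astype(float)
        total = x.sum()
        rows.append(
            {
                "low_sd": np.std(x, ddof=1) < 1.0,
                "high_zero_fraction": (x == 0).mean() >= 0.90,
                "mito_hb_fraction": (
                    (x[special_mask].sum() / total if total > 0 else 1.0) >= 0.10
                ),
                "umi_range": total < 100 or total > 20_000,
            }
        )
    return pd.DataFrame(rows)
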