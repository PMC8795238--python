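"""Per-cell hotspot variant allele frequencies and enrichment tests.

Allele counts arrive as a tidy table of per-(cell, variant) ref/alt read
counts (the output shape of read-level extractors such as VarTrix).  VAF is
alt / (alt + ref) where the site is covered; a cell is "mutated" at a
variant if it has at least one alt read.  Variants outside the hotspot
catalog, or with zero alt reads everywhere, are dropped, and immune cells
are excluded from tabulation.  Cell-type enrichment uses Fisher's exact
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import io as gio

AC_COLUMNS = ["cell_id", "variant_id", "ref", "alt"]


def load_catalog(path=None) -> pd.DataFrame:
    """Load a hotspot catalog TSV (variant_id, gene, position, protein_change,
    pathway); defaults to the bundled synthetic catalog."""
    path = path or gio.packaged_data("hotspots_synthetic.tsv")
    cat = pd.read_csv(path, sep="\t")
    if cat["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in catalog")
    if (cat["position"] <= 0).any():
        raise ValueError("variant positions must be positive")
    return cat


def _check_counts(ac: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in AC_COLUMNS if c not in ac.columns]
    if missing:
        raise ValueError(f"allele count table missing columns: {missing}")
    if (ac["ref"] < 0).any() or (ac["alt"] < 0).any():
        raise ValueError("negative allele counts")
    return ac


def tabulate_vaf(ac: pd.DataFrame) -> pd.DataFrame:
    """VAF = alt / (alt + ref) per covered (cell, variant).

    Rows with zero depth are returned with VAF = NaN (site present but not
    covered); ``mutated`` flags alt >= 1.
    """
    ac = _check_counts(ac).copy()
    depth = ac["alt"] + ac["ref"]
    with np.errstate(invalid="ignore"):
        ac["vaf"] = np.where(depth > 0, ac["alt"] / depth.where(depth > 0, 1), np.nan)
    ac["mutated"] = ac["alt"] >= 1
    return ac


def filter_hotspot_variants(
    ac: pd.DataFrame,
    catalog: pd.DataFrame,
    compartment: pd.Series | None = None,
) -> pd.DataFrame:
    """Restrict to catalog variants with evidence, outside immune cells.

    Keeps only variants present in the catalog; drops variants with zero alt
    reads across all cells; removes rows from cells labeled "immune" in
    ``compartment`` (a per-cell Series) before downstream tabulation.
    """
    if catalog.empty:
        raise ValueError("empty hotspot catalog")
    ac = _check_counts(ac)
    ac = ac[ac["variant_id"].isin(catalog["variant_id"])]
    if compartment is not None:
        immune = set(compartment.index[compartment == "immune"])
        ac = ac[~ac["cell_id"].isin(immune)]
    seen_alt = ac.groupby("variant_id")["alt"].sum()
    keep = set(seen_alt.index[seen_alt > 0])
    return ac[ac["variant_id"].isin(keep)].reset_index(drop=True)


def mutation_by_celltype(
    ac: pd.DataFrame,
    annotations: pd.Series,
    catalog: pd.DataFrame,
    lesions: pd.Series | None = None,
) -> pd.DataFrame:
    """Mutated-cell counts per gene and cell type (optionally per lesion).

    A cell counts once per gene if it has >= 1 alt read at any of the gene's
    variants.  Cells without an annotation are tallied as "unassigned".
    """
    vaf = tabulate_vaf(ac)
    vaf = vaf[vaf["mutated"]]
    gene_of = dict(zip(catalog["variant_id"], catalog["gene"]))
    vaf = vaf.assign(gene=vaf["variant_id"].map(gene_of))
    ann = annotations.reindex(vaf["cell_id"]).fillna("unassigned").to_numpy()
    vaf = vaf.assign(cell_type=ann)
    if lesions is not None:
        vaf = vaf.assign(lesion=lesions.reindex(vaf["cell_id"]).to_numpy())
        keys = ["gene", "cell_type", "lesion"]
    else:
        keys = ["gene", "cell_type"]
    counts = (
        vaf.drop_duplicates(["cell_id", "gene"] + (["lesion"] if lesions is not None else []))
        .groupby(keys, observed=True)
        .size()
        .rename("n_mutated_cells")
        .reset_index()
    )
    return counts


def enrichment_fisher(table: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p, degenerate).  The odds ratio uses a Haldane 0.5
    correction when any cell is zero.  A zero row or column margin is
    degenerate: p = 1 by convention, flagged via the third element.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b, c, d = t.ravel()
    degenerate = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if degenerate:
        return 1.0, 1.0, True
    if min(a, b, c, d) == 0:
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orat = a * d / (b * c)
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    return float(orat), p, False
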