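"""Expression-inferred copy-number scoring along genomic position.

Malignant cells are distinguished from normal ones by coherent shifts of
expression over contiguous genomic regions.  The score is the standard
moving-window construction: order genes by (chromosome, start), center each
gene on the mean of a reference (non-malignant) cell set, clip extreme
residuals, smooth with a centered moving average within each chromosome,
re-center each cell at its median, and finally re-center genes on the
reference cells so reference scores average to zero exactly.  A per-cell
burden (mean squared score) summarizes total copy-number signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CNVMatrix:
    """Per-cell, per-gene copy-number scores (genes in genomic order)."""

    values: pd.DataFrame  # cells x genes (ordered by chromosome, start)
    gene_order: pd.DataFrame  # feature rows in genomic order
    window: int
    reference_cells: list[str]

    @property
    def burden(self) -> pd.Series:
        """Mean squared score per cell."""
        return (self.values**2).mean(axis=1).rename("cnv_burden")


def _moving_average_by_chrom(
    mat: np.ndarray, chroms: np.ndarray, window: int
) -> np.ndarray:
    """Centered moving average of width ``window`` within each chromosome.

    Edge positions average over the genes available (truncated window); a
    chromosome shorter than the window is averaged over what it has.
    """
    half = window // 2
    out = np.empty_like(mat)
    for c in pd.unique(chroms):
        cols = np.flatnonzero(chroms == c)
        block = mat[:, cols]
        n = block.shape[1]
        if n < window:
            warnings.warn(
                f"chromosome {c} has {n} genes < window {window}; truncated", stacklevel=2
            )
        csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out[:, cols] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv_scores(
    norm: ad.AnnData,
    reference_cells: list[str] | np.ndarray,
    window: int = 101,
    clip: float = 3.0,
) -> CNVMatrix:
    """Moving-window copy-number scores from normalized expression.

    ``reference_cells`` are barcodes of presumed copy-neutral cells (e.g.
    non-malignant epithelial/stromal annotations); their per-gene mean
    defines zero.  Requires chromosome/start coordinates for at least half
    the genes; genes without coordinates are dropped.
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    var = norm.var
    has_coord = var["chromosome"].notna() & var["start"].notna()
    if has_coord.mean() < 0.5:
        raise ValueError("missing genomic coordinates for more than 50% of genes")
    order = (
        var[has_coord]
        .rename_axis(index=None)
        .sort_values(["chromosome", "start", "gene_id"], kind="stable")
    )
    order.index.name = "gene_id_index"
    X = np.asarray(sp.csr_matrix(norm[:, order.index].X).todense())
    ref_idx = norm.obs_names.get_indexer(reference_cells)
    if (ref_idx < 0).any():
        raise ValueError("reference cell not found in matrix")

    centered = X - X[ref_idx].mean(axis=0)
    centered = np.clip(centered, -clip, clip)
    smoothed = _moving_average_by_chrom(centered, order["chromosome"].to_numpy(), window)
    smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)
    smoothed = smoothed - smoothed[ref_idx].mean(axis=0)  # exact reference zero

    values = pd.DataFrame(smoothed, index=norm.obs_names, columns=order.index)
    return CNVMatrix(values=values, gene_order=order, window=window,
                     reference_cells=reference_cells)


def call_gene_cnv(
    cnv: CNVMatrix,
    genes: list[str],
    clusters: np.ndarray | pd.Series,
    threshold: float = 0.15,
) -> pd.DataFrame:
    """Per-cluster amplification/deletion calls at named genes.

    A gene is called ``amp`` in a cluster if the cluster-mean score exceeds
    +threshold, ``del`` below -threshold, ``neutral`` otherwise.  Genes
    absent from the feature table are reported with call ``missing`` rather
    than silently dropped.  ``genes`` are symbols.
    """
    clusters = pd.Series(np.asarray(clusters), index=cnv.values.index)
    sym_to_id = dict(zip(cnv.gene_order["symbol"], cnv.gene_order.index))
    rows = []
    for g in genes:
        gid = sym_to_id.get(g)
        if gid is None:
            rows.append({"gene": g, "cluster": pd.NA, "mean_score": np.nan, "call": "missing"})
            continue
        means = cnv.values[gid].groupby(clusters).mean()
        for cl, m in means.items():
            call = "amp" if m > threshold else ("del" if m < -threshold else "neutral")
            rows.append({"gene": g, "cluster": cl, "mean_score": float(m), "call": call})
    return pd.DataFrame(rows)
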