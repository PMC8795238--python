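"""Cell quality control, depth normalization, and the immune/non-immune split.

Low-quality droplets are removed by four per-cell rules evaluated on raw UMI
counts:

1. ``low_sd`` — standard deviation of counts across all genes below 1
   (near-constant profile, typically empty or degraded droplets);
2. ``high_zero_fraction`` — 90% or more of genes with zero count;
3. ``mito_hb_fraction`` — 10% or more of UMIs from mitochondrial or
   hemoglobin genes (lysed cells, erythrocyte contamination);
4. ``umi_range`` — total UMI below 100 (empty droplet) or above 20,000
   (likely multiplet).

Surviving cells are depth-normalized: counts are divided by the cell's total
UMI, multiplied by a common scale factor (default 10,000) and log1p
transformed.  After normalization, preliminary clusters are split into immune
and non-immune compartments by average PTPRC (CD45) expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

QC_RULES = ("low_sd", "high_zero_fraction", "mito_hb_fraction", "umi_range")


class EmptyAfterQCError(ValueError):
    """Every cell violated at least one QC rule."""


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the four low-quality-cell rules.

    Boundary conventions: the zero-count and mito/hemoglobin fractions remove
    at the threshold itself (>= 0.90, >= 0.10); the UMI rule is strict
    (< 100 or > 20,000); the stddev rule is strict (< 1).
    """

    stddev_floor: float = 1.0
    zero_fraction_ceiling: float = 0.90
    mito_hb_fraction_ceiling: float = 0.10
    umi_floor: float = 100
    umi_ceiling: float = 20_000

    def __post_init__(self):
        if self.umi_floor >= self.umi_ceiling:
            raise ValueError("umi_floor must be < umi_ceiling")
        for f in (self.zero_fraction_ceiling, self.mito_hb_fraction_ceiling):
            if not 0 <= f <= 1:
                raise ValueError("fraction thresholds must lie in [0, 1]")


def evaluate_qc_rules(counts: ad.AnnData, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Evaluate the four rules for every cell.

    Returns a boolean DataFrame (cells x rules); True means the rule fires
    and the cell is low quality.  Per-cell stddev uses sample sd (ddof=1) on
    raw counts.
    """
    X = sp.csr_matrix(counts.X)
    n_cells, n_genes = X.shape
    if n_cells == 0 or n_genes == 0:
        raise ValueError("empty count matrix")
    for col in ("mito", "hemoglobin"):
        if col not in counts.var:
            raise ValueError(f"feature flag column {col!r} missing")

    total = np.asarray(X.sum(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    # sample variance across all genes, zeros included
    var = (sq - total**2 / n_genes) / (n_genes - 1) if n_genes > 1 else np.zeros(n_cells)
    sd = np.sqrt(np.maximum(var, 0))
    nnz = X.getnnz(axis=1)
    zero_frac = 1.0 - nnz / n_genes
    special = (counts.var["mito"] | counts.var["hemoglobin"]).to_numpy()
    special_umi = np.asarray(X[:, special].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        special_frac = np.where(total > 0, special_umi / np.maximum(total, 1), 1.0)

    return pd.DataFrame(
        {
            "low_sd": sd < cfg.stddev_floor,
            "high_zero_fraction": zero_frac >= cfg.zero_fraction_ceiling,
            "mito_hb_fraction": special_frac >= cfg.mito_hb_fraction_ceiling,
            "umi_range": (total < cfg.umi_floor) | (total > cfg.umi_ceiling),
        },
        index=counts.obs_names,
    )


def filter_cells(
    counts: ad.AnnData, cfg: QCConfig = QCConfig()
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove cells violating any QC rule.

    Returns the kept AnnData and a report listing, for every *removed* cell,
    the rules it violated (one row per cell, comma-joined rule ids).
    Raises :class:`EmptyAfterQCError` if nothing survives.
    """
    fired = evaluate_qc_rules(counts, cfg)
    bad = fired.any(axis=1)
    report = pd.DataFrame(
        {
            "barcode": fired.index[bad],
            "violated_rules": [
                ",".join(r for r in QC_RULES if fired.loc[c, r]) for c in fired.index[bad]
            ],
        }
    ).reset_index(drop=True)
    if bad.all():
        raise EmptyAfterQCError("all cells removed: empty after QC")
    kept = counts[~bad.to_numpy()].copy()
    kept.uns["qc_config"] = cfg.__dict__.copy()
    return kept, report


def normalize_log(counts: ad.AnnData, scale_factor: float = 10_000) -> ad.AnnData:
    """Depth-normalize and log-transform: log1p(count / total * scale_factor)."""
    X = sp.csr_matrix(counts.X, dtype=float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total <= 0):
        raise ValueError("cell with zero total UMI; run filter_cells first")
    norm = sp.diags(scale_factor / total) @ X
    norm.data = np.log1p(norm.data)
    out = ad.AnnData(X=norm.tocsr(), obs=counts.obs.copy(), var=counts.var.copy())
    out.uns.update(counts.uns)
    out.uns["scale_factor"] = float(scale_factor)
    out.layers["counts"] = sp.csr_matrix(counts.X)
    return out


def split_immune(
    norm: ad.AnnData,
    clusters: pd.Series | np.ndarray,
    ptprc_symbol: str = "PTPRC",
) -> pd.Series:
    """Partition cells into immune / non-immune compartments.

    A cluster is called immune iff its mean PTPRC (CD45) expression strictly
    exceeds the global mean across all cells; all member cells inherit the
    call.  Returns a per-cell Series with values "immune" / "non_immune".
    """
    hits = np.flatnonzero((norm.var["symbol"] == ptprc_symbol).to_numpy())
    if hits.size == 0:
        raise ValueError(f"feature {ptprc_symbol!r} absent from the gene universe")
    expr = np.asarray(sp.csr_matrix(norm.X)[:, hits[0]].todense()).ravel()
    clusters = pd.Series(np.asarray(clusters), index=norm.obs_names, name="cluster")
    global_mean = expr.mean()
    cluster_means = pd.Series(expr, index=norm.obs_names).groupby(clusters).mean()
    immune_clusters = set(cluster_means.index[cluster_means > global_mean])
    labels = clusters.map(lambda c: "immune" if c in immune_clusters else "non_immune")
    return labels.rename("compartment")
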