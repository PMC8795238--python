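"""Variable-gene selection, graph clustering, marker testing and cell typing.

Highly variable genes are chosen by mean-binned standardized dispersion
(the classic Seurat FindVariableGenes procedure, cutoffs 0.0125 < mean < 6,
dispersion z > 0.5).  Cells are embedded by PCA on the scaled HVG submatrix,
connected in a shared-nearest-neighbor (SNN) graph with Jaccard edge weights,
and partitioned by Louvain modularity at a configurable resolution.  Cluster
markers come from one-vs-rest Wilcoxon rank-sum tests; clusters are assigned
cell types against a literature-marker table; per-sample composition is
compared between groups with t tests and two-proportion z tests.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest


@dataclass(frozen=True)
class HVGConfig:
    mean_low: float = 0.0125
    mean_high: float = 6.0
    dispersion_cutoff: float = 0.5
    n_bins: int = 20

    def __post_init__(self):
        if self.mean_low >= self.mean_high:
            raise ValueError("mean_low must be < mean_high")


@dataclass(frozen=True)
class ClusterConfig:
    n_pcs_compute: int = 30
    n_pcs_use: int = 20
    resolution: float = 0.8
    knn_k: int = 20
    seed: int = 12345

    def __post_init__(self):
        if self.n_pcs_use > self.n_pcs_compute:
            raise ValueError("n_pcs_use must be <= n_pcs_compute")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


def select_hvg(norm: ad.AnnData, cfg: HVGConfig = HVGConfig()) -> list[str]:
    """Highly variable genes by binned-standardized dispersion.

    Mean and dispersion (log of variance/mean ratio) are computed on the
    de-logged normalized values; dispersions are z-scored within equal-width
    mean bins.  Genes pass with mean in (mean_low, mean_high) and
    standardized dispersion above the cutoff.  Returns gene ids.
    """
    if norm.n_obs < 2:
        raise ValueError("need at least 2 cells")
    X = sp.csr_matrix(norm.X)
    if X.nnz == 0 or (X.max() == X.min()):
        warnings.warn("all genes constant; no variable genes", stacklevel=2)
        return []
    tmp = ad.AnnData(X=X.copy(), var=norm.var.copy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            tmp,
            flavor="seurat",
            min_mean=cfg.mean_low,
            max_mean=cfg.mean_high,
            min_disp=cfg.dispersion_cutoff,
            n_bins=cfg.n_bins,
        )
    return list(tmp.var_names[tmp.var["highly_variable"]])


def _scaled_submatrix(norm: ad.AnnData, genes: list[str], clip: float = 10.0) -> np.ndarray:
    sub = np.asarray(sp.csr_matrix(norm[:, genes].X).todense())
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.clip((sub - mu) / sd, -clip, clip)


def snn_graph(pcs: np.ndarray, k: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell is linked to its k nearest Euclidean neighbors (self included);
    edge weight between two cells is the Jaccard overlap of their neighbor
    sets; zero-overlap edges are dropped.
    """
    n = pcs.shape[0]
    if n <= k:
        raise ValueError(f"need more cells than knn_k={k}")
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    adj = nn.kneighbors_graph(pcs, mode="connectivity")  # n x n binary, incl self
    shared = adj @ adj.T
    shared = sp.coo_matrix(shared)
    jac = shared.data / (2 * k - shared.data)
    out = sp.coo_matrix((jac, (shared.row, shared.col)), shape=(n, n)).tocsr()
    out.setdiag(0)
    out.eliminate_zeros()
    return out


def _louvain(graph: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(graph, k=1).tocoo()
    g = igraph.Graph(
        n=graph.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    state = igraph.set_random_number_generator
    state(_random.Random(seed))
    try:
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        state(_random._inst)  # restore module default
    return np.asarray(part.membership)


def embed_and_cluster(
    norm: ad.AnnData, hvg: list[str], cfg: ClusterConfig = ClusterConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """PCA embedding + Louvain communities on the SNN graph.

    Returns (embedding cells x n_pcs_compute, integer labels 0..K-1 ordered
    by decreasing cluster size).
    """
    if len(hvg) < cfg.n_pcs_compute:
        raise ValueError(
            f"need at least n_pcs_compute={cfg.n_pcs_compute} variable genes, got {len(hvg)}"
        )
    scaled = _scaled_submatrix(norm, hvg)
    pca = PCA(n_components=cfg.n_pcs_compute, svd_solver="full", random_state=cfg.seed)
    emb = pca.fit_transform(scaled)
    graph = snn_graph(emb[:, : cfg.n_pcs_use], cfg.knn_k)
    raw = _louvain(graph, cfg.resolution, cfg.seed)
    order = pd.Series(raw).value_counts().index  # by size, ties by first occurrence
    remap = {old: new for new, old in enumerate(order)}
    return emb, np.array([remap[r] for r in raw], dtype=int)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value; exact for small
    tie-free samples, normal approximation otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def _log_fold_change(in_vals: np.ndarray, out_vals: np.ndarray) -> float:
    # natural-log FC of de-logged means, the convention the 0.25 cutoff assumes
    return float(np.log(np.expm1(in_vals).mean() + 1) - np.log(np.expm1(out_vals).mean() + 1))


def find_markers(
    norm: ad.AnnData,
    clusters: np.ndarray | pd.Series,
    min_fraction: float = 0.25,
    lfc_threshold: float = 0.25,
    fdr_threshold: float = 0.01,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker tests per cluster.

    Genes detected in at least ``min_fraction`` of in-cluster cells with
    natural-log fold change >= ``lfc_threshold`` are tested.  Bonferroni uses
    the full gene universe; FDR is Benjamini–Hochberg over all performed
    tests.  ``is_marker`` requires >= ``fold_threshold``-fold up-regulation
    and FDR < ``fdr_threshold``.  Singleton clusters are skipped (recorded
    with gene = NA).
    """
    clusters = np.asarray(clusters)
    if len(np.unique(clusters)) < 2:
        raise ValueError("need at least 2 clusters")
    X = np.asarray(sp.csr_matrix(norm.X).todense())
    m_total = X.shape[1]
    rows = []
    for cl in np.unique(clusters):
        mask = clusters == cl
        if mask.sum() < 2:
            rows.append({"gene": pd.NA, "cluster": cl, "log_fold_change": np.nan,
                         "fraction_in": np.nan, "fraction_out": np.nan,
                         "p_raw": np.nan, "skipped": True})
            continue
        inX, outX = X[mask], X[~mask]
        frac_in = (inX > 0).mean(axis=0)
        candidates = np.flatnonzero(frac_in >= min_fraction)
        for j in candidates:
            lfc = _log_fold_change(inX[:, j], outX[:, j])
            if lfc < lfc_threshold:
                continue
            rows.append({
                "gene": norm.var_names[j], "cluster": cl, "log_fold_change": lfc,
                "fraction_in": float(frac_in[j]),
                "fraction_out": float((outX[:, j] > 0).mean()),
                "p_raw": wilcoxon_rank_sum(inX[:, j], outX[:, j]),
                "skipped": False,
            })
    degs = pd.DataFrame(rows)
    if degs.empty:
        return degs.assign(p_bonferroni=[], fdr=[], is_marker=[])
    tested = ~degs["skipped"]
    degs["p_bonferroni"] = np.minimum(degs["p_raw"] * m_total, 1.0)
    degs["fdr"] = np.nan
    if tested.any():
        degs.loc[tested, "fdr"] = multipletests(
            degs.loc[tested, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]
    degs["is_marker"] = tested & (degs["log_fold_change"] >= np.log(fold_threshold)) & (
        degs["fdr"] < fdr_threshold
    )
    return degs


def assign_cell_types(
    norm: ad.AnnData,
    clusters: np.ndarray | pd.Series,
    marker_table: dict[str, list[str]],
) -> tuple[dict[int, str], pd.DataFrame]:
    """Assign each cluster the cell type whose markers it expresses most.

    Score(cluster, type) = mean over the type's present markers of the
    cluster-mean z-scored expression.  Ties break by number of detected
    markers, then lexicographic type name.  A cluster with zero raw
    expression of every marker gene is "unassigned".
    Returns (cluster -> type map, score matrix clusters x types).
    """
    if not marker_table:
        raise ValueError("empty marker table")
    clusters = np.asarray(clusters)
    X = np.asarray(sp.csr_matrix(norm.X).todense())
    sym = norm.var["symbol"].astype(str).to_numpy()
    pos = {s: i for i, s in enumerate(sym)}
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    cluster_ids = np.unique(clusters)
    scores = pd.DataFrame(index=cluster_ids, columns=sorted(marker_table), dtype=float)
    detected = pd.DataFrame(0, index=cluster_ids, columns=sorted(marker_table))
    all_marker_idx = sorted({pos[m] for ms in marker_table.values() for m in ms if m in pos})
    assignment: dict[int, str] = {}
    for cl in cluster_ids:
        mask = clusters == cl
        if not all_marker_idx or X[np.ix_(mask, all_marker_idx)].sum() == 0:
            assignment[cl] = "unassigned"
            scores.loc[cl] = np.nan
            continue
        for t in sorted(marker_table):
            idx = [pos[m] for m in marker_table[t] if m in pos]
            if not idx:
                scores.loc[cl, t] = -np.inf
                continue
            scores.loc[cl, t] = Z[np.ix_(mask, idx)].mean()
            detected.loc[cl, t] = int((X[np.ix_(mask, idx)].sum(axis=0) > 0).sum())
        row = scores.loc[cl].astype(float)
        best = row.max()
        tied = sorted(row.index[row == best])
        if len(tied) > 1:
            ov = detected.loc[cl, tied]
            tied = sorted(ov.index[ov == ov.max()])
        assignment[cl] = tied[0]
    return assignment, scores


def celltype_frequency_test(
    annotations: pd.DataFrame,
    group_col: str = "group",
    sample_col: str = "sample",
    type_col: str = "cell_type",
) -> pd.DataFrame:
    """Two-sample t tests of per-sample cell-type frequencies between groups.

    ``annotations`` has one row per cell.  Frequencies are computed per
    sample (rows sum to 1) and compared between the two groups per cell
    type.  Groups with fewer than 2 samples are skipped with a notice row.
    """
    groups = annotations[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    freq = (
        annotations.groupby([sample_col, type_col], observed=True).size().unstack(fill_value=0)
    )
    freq = freq.div(freq.sum(axis=1), axis=0)
    sample_group = annotations.drop_duplicates(sample_col).set_index(sample_col)[group_col]
    rows = []
    a_samples = freq.index[sample_group.reindex(freq.index) == groups[0]]
    b_samples = freq.index[sample_group.reindex(freq.index) == groups[1]]
    for ct in freq.columns:
        a, b = freq.loc[a_samples, ct], freq.loc[b_samples, ct]
        if len(a) < 2 or len(b) < 2:
            rows.append({"cell_type": ct, "mean_a": a.mean(), "mean_b": b.mean(),
                         "t": np.nan, "p": np.nan, "note": "group with <2 samples"})
            continue
        if np.allclose(a.to_numpy()[:, None], b.to_numpy()[None, :]) and a.var() == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({"cell_type": ct, "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                     "t": float(t), "p": float(p), "note": ""})
    return pd.DataFrame(rows)


def cluster_composition_test(
    annotations: pd.DataFrame,
    cluster_col: str = "cluster",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-cluster two-proportion z test of group composition.

    For each cluster, compares the fraction of each group's cells falling in
    the cluster (cells-in-cluster / group total) between the two groups.
    """
    groups = annotations[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    totals = annotations[group_col].value_counts()
    rows = []
    for cl, sub in annotations.groupby(cluster_col, observed=True):
        counts = np.array([
            (sub[group_col] == groups[0]).sum(), (sub[group_col] == groups[1]).sum()
        ])
        nobs = np.array([totals[groups[0]], totals[groups[1]]])
        if counts.sum() == 0 or (counts == nobs).all():
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest(counts, nobs)
        rows.append({"cluster": cl, f"n_{groups[0]}": counts[0], f"n_{groups[1]}": counts[1],
                     "z": float(z), "p": float(p)})
    return pd.DataFrame(rows)
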