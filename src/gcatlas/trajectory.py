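"""Pseudotime trajectories, progression states, and pseudotime-dependent genes.

Cells are reduced to two dimensions (PCA then ICA), summarized by k
representative cells ("medoids": k-means centers snapped to the nearest real
cell), and connected by a minimum spanning tree.  Pseudotime is the tree
geodesic distance from a root medoid — chosen as the medoid richest in
configured benign cell types — plus the cell's local offset to its medoid.
Branch segments are maximal tree paths between branch points.  Cells are
then divided into ordered progression states (the I1–I3 / D1–D4 style
grouping) by equal-count pseudotime quantiles, with excluded stromal types
(fibroblast, EC) given their own terminal labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from patsy import dmatrix
from scipy import stats
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA
from sklearn.metrics import pairwise_distances


@dataclass
class Trajectory:
    cell_ids: pd.Index
    embedding: np.ndarray  # cells x 2
    medoid_cells: np.ndarray  # indices into cell_ids, one per tree node
    edges: list[tuple[int, int, float]]  # MST over medoids
    root: int  # medoid (node) index
    medoid_of_cell: np.ndarray  # node index per cell
    pseudotime: pd.Series
    branch_state: pd.Series

    def to_newick(self) -> str:
        """Serialize the medoid tree (rooted at the root medoid) as Newick."""
        children: dict[int, list[tuple[int, float]]] = {}
        for a, b, w in self.edges:
            children.setdefault(a, []).append((b, w))
            children.setdefault(b, []).append((a, w))

        def walk(node: int, parent: int) -> str:
            kids = [(c, w) for c, w in children.get(node, []) if c != parent]
            label = f"m{node}"
            if not kids:
                return label
            inner = ",".join(f"{walk(c, node)}:{w:.4f}" for c, w in kids)
            return f"({inner}){label}"

        return walk(self.root, -1) + ";"


def _reduce_2d(
    norm: ad.AnnData, hvg: list[str], n_pcs: int, seed: int, reduction: str = "pca"
) -> np.ndarray:
    """2-D reduction of the scaled HVG submatrix: plain PCA (default) or
    PCA followed by ICA."""
    X = np.asarray(sp.csr_matrix(norm[:, hvg].X).todense())
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if reduction == "pca":
        return PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(Xs)
    if reduction == "ica":
        n_pcs = min(n_pcs, Xs.shape[1], Xs.shape[0] - 1)
        pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(Xs)
        ica = FastICA(n_components=2, random_state=seed, whiten="unit-variance", max_iter=1000)
        return ica.fit_transform(pcs)
    raise ValueError(f"unknown reduction {reduction!r}")


def build_trajectory(
    norm: ad.AnnData,
    hvg: list[str],
    root_rule: list[str] | int,
    annotations: pd.Series | None = None,
    n_medoids: int = 30,
    n_pcs: int = 10,
    seed: int = 12345,
    reduction: str = "pca",
) -> Trajectory:
    """MST pseudotime over medoid centroids in a 2-D reduction.

    ``root_rule`` is either an explicit medoid node index or a list of
    benign cell-type names; in the latter case the root is the medoid whose
    assigned cells have the highest proportion of those types (requires
    ``annotations``, a per-cell type Series).
    """
    if norm.n_obs < 3:
        raise ValueError("need at least 3 cells")
    # canonical cell order (sorted barcodes) so results don't depend on input order
    order = np.argsort(norm.obs_names)
    norm = norm[order].copy()
    if annotations is not None:
        if isinstance(annotations, pd.Series):
            annotations = annotations.reindex(norm.obs_names)
        else:
            annotations = pd.Series(np.asarray(annotations)[order], index=norm.obs_names)
    emb = _reduce_2d(norm, hvg, n_pcs, seed, reduction)
    k = min(n_medoids, norm.n_obs)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    # snap each center to the nearest actual cell (medoid)
    d_center = pairwise_distances(km.cluster_centers_, emb)
    medoid_cells = np.array([int(np.argmin(row)) for row in d_center])
    med_emb = emb[medoid_cells]
    assign = np.argmin(pairwise_distances(emb, med_emb), axis=1)

    dist = pairwise_distances(med_emb)
    mst = minimum_spanning_tree(dist)
    mst_sym = mst + mst.T
    coo = sp.coo_matrix(mst)
    edges = [(int(a), int(b), float(w)) for a, b, w in zip(coo.row, coo.col, coo.data)]

    if isinstance(root_rule, int):
        root = root_rule
        if not 0 <= root < k:
            raise ValueError(f"root medoid {root} out of range")
    else:
        if annotations is None:
            raise ValueError("type-based root rule requires annotations")
        ann = pd.Series(np.asarray(annotations), index=norm.obs_names)
        props = np.array([
            ann.iloc[np.flatnonzero(assign == m)].isin(root_rule).mean()
            if (assign == m).any() else 0.0
            for m in range(k)
        ])
        if props.max() == 0:
            raise ValueError(f"root rule {root_rule!r} matches no medoid")
        root = int(np.argmax(props))

    geo = shortest_path(mst_sym, indices=root)
    offset = np.linalg.norm(emb - med_emb[assign], axis=1)
    pt = geo[assign] + offset
    pt[medoid_cells[root]] = 0.0

    branch = _branch_segments(mst_sym, k)
    pseudotime = pd.Series(pt, index=norm.obs_names, name="pseudotime")
    branch_state = pd.Series(branch[assign], index=norm.obs_names, name="branch_state")
    return Trajectory(
        cell_ids=norm.obs_names, embedding=emb, medoid_cells=medoid_cells,
        edges=edges, root=root, medoid_of_cell=assign,
        pseudotime=pseudotime, branch_state=branch_state,
    )


def _branch_segments(mst_sym: sp.spmatrix, n_nodes: int) -> np.ndarray:
    """Label tree nodes by segment between branch points.

    Branch points (degree >= 3) are removed; connected components of the
    remainder are segments; each branch point joins its lowest-numbered
    neighboring segment.
    """
    adj = (mst_sym != 0).astype(int)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    branch_nodes = np.flatnonzero(deg >= 3)
    keep = np.setdiff1d(np.arange(n_nodes), branch_nodes)
    sub = adj[np.ix_(keep, keep)]
    n_comp, comp = connected_components(sub, directed=False)
    labels = np.full(n_nodes, -1, dtype=int)
    labels[keep] = comp
    for b in branch_nodes:
        nbrs = np.flatnonzero(np.asarray(adj[b].todense()).ravel())
        nbr_labels = [labels[x] for x in nbrs if labels[x] >= 0]
        labels[b] = min(nbr_labels) if nbr_labels else n_comp
    return labels


def assign_progression_states(
    traj: Trajectory,
    annotations: pd.Series,
    n_states: int,
    exclude_types: list[str] = (),
    prefix: str = "S",
) -> pd.Series:
    """Ordered progression states by pseudotime quantiles.

    Excluded types (e.g. fibroblast, EC) receive their own terminal labels
    ("excluded:<type>").  Remaining cells are split into ``n_states``
    equal-count pseudotime bins; state labels (prefix + 1..n) are ordered so
    that mean pseudotime is non-decreasing.  Branch membership is available
    in ``traj.branch_state`` for branch-resolved cross-tabulation.
    """
    if isinstance(annotations, pd.Series):
        ann = annotations.reindex(traj.cell_ids)
    else:
        raise TypeError("annotations must be a per-cell Series indexed by barcode")
    excluded = ann.isin(list(exclude_types))
    included = ~excluded
    n_inc = int(included.sum())
    if n_states > max(n_inc, 0):
        raise ValueError(f"n_states={n_states} exceeds {n_inc} assignable cells")
    labels = pd.Series(index=traj.cell_ids, dtype=object, name="state")
    labels[excluded] = "excluded:" + ann[excluded].astype(str)
    if n_inc:
        pt = traj.pseudotime[included]
        ranks = pt.rank(method="first") - 1
        bins = np.floor(ranks * n_states / n_inc).astype(int).clip(0, n_states - 1)
        labels[included] = [f"{prefix}{b + 1}" for b in bins]
    return labels


def pseudotime_deg_lrt(
    norm: ad.AnnData, pseudotime: pd.Series | np.ndarray, df: int = 3
) -> pd.DataFrame:
    """Likelihood-ratio test for pseudotime-dependent expression per gene.

    A Gaussian working model on the log-normalized scale compares a natural
    cubic spline of pseudotime (``df`` degrees of freedom) against an
    intercept; the LRT statistic n*log(RSS0/RSS1) is referred to chi-square
    with ``df`` degrees of freedom.  Constant genes get p = 1.
    """
    t = np.asarray(pseudotime, float)
    n = len(t)
    if n != norm.n_obs:
        raise ValueError("pseudotime must cover all tested cells")
    basis = np.asarray(dmatrix(f"cr(t, df={df})", {"t": t}, return_type="matrix"))
    Q, _ = np.linalg.qr(basis)
    Y = np.asarray(sp.csr_matrix(norm.X).todense())
    Yc = Y - Y.mean(axis=0)
    rss0 = (Yc**2).sum(axis=0)
    resid = Y - Q @ (Q.T @ Y)
    rss1 = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(rss0 / rss1)
    p = stats.chi2.sf(lrt, df)
    constant = rss0 <= 1e-12
    p = np.where(constant, 1.0, p)
    return pd.DataFrame(
        {"lrt": np.where(constant, 0.0, lrt), "p": p}, index=norm.var_names
    )


def state_overlap(degs_a: set[str], degs_b: set[str]) -> tuple[float, list[str]]:
    """Percentage of set A's genes shared with set B, plus the intersection.

    Returns (100 * |A ∩ B| / |A|, sorted intersection)."""
    a, b = set(degs_a), set(degs_b)
    if not a or not b:
        raise ValueError("both gene sets must be nonempty")
    inter = sorted(a & b)
    return 100.0 * len(inter) / len(a), inter
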