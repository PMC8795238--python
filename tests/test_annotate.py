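"""HVG selection, clustering, marker testing, typing, composition tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from gcatlas import annotate, io as gio, preprocess, synthetic
from gcatlas.annotate import (
    ClusterConfig,
    HVGConfig,
    assign_cell_types,
    celltype_frequency_test,
    cluster_composition_test,
    embed_and_cluster,
    find_markers,
    select_hvg,
    wilcoxon_rank_sum,
)

from conftest import three_type_config


def _norm_from_dense(X, symbols=None):
    n_genes = X.shape[1]
    symbols = symbols or [f"G{i}" for i in range(n_genes)]
    feats = pd.DataFrame({
        "gene_id": [f"E{i}" for i in range(n_genes)], "symbol": symbols,
        "chromosome": "chr1", "start": np.arange(1, n_genes + 1),
    })
    adata = gio.make_anndata(sp.csr_matrix(X.astype(int)),
                             [f"c{i}" for i in range(X.shape[0])], feats)
    return preprocess.normalize_log(adata)


@pytest.fixture(scope="module")
def clustered_sim():
    cfg = three_type_config(seed=23)
    adata, truth = synthetic.simulate_cells(cfg)
    kept, _ = preprocess.filter_cells(adata)
    norm = preprocess.normalize_log(kept)
    hvg = select_hvg(norm)
    tt = truth.cells.loc[kept.obs_names, "true_type"]
    return norm, hvg, tt


class TestSelectHVG:
    def test_zero_variance_gene_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5, size=(100, 50))
        X[:, 0] = 0  # constant (zero) on every scale
        norm = _norm_from_dense(X)
        hvg = select_hvg(norm)
        assert "E0" not in hvg

    def test_low_mean_gene_excluded_regardless_of_dispersion(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(300, 60))
        X[:, 0] = 0
        X[::150, 0] = 2  # rare spikes: mean far below cutoff, dispersion huge
        norm = _norm_from_dense(X)
        hvg = select_hvg(norm, HVGConfig(mean_low=0.5))
        assert "E0" not in hvg

    def test_planted_overdispersed_genes_recovered(self):
        rng = np.random.default_rng(2)
        n, flat, noisy = 500, 180, 20
        # flat genes span a range of means so dispersion bins are well mixed
        base = rng.poisson(rng.uniform(1, 30, size=flat), size=(n, flat))
        # overdispersed genes scattered over the same mean range
        od_means = rng.uniform(2, 25, size=noisy)
        lam = rng.gamma(0.15, od_means / 0.15, size=(n, noisy))
        od = rng.poisson(lam)
        norm = _norm_from_dense(np.hstack([base, od]))
        hvg = set(select_hvg(norm))
        planted = {f"E{i}" for i in range(flat, flat + noisy)}
        assert len(hvg & planted) / noisy > 0.9


class TestEmbedAndCluster:
    def test_three_planted_types_recovered(self, clustered_sim):
        norm, hvg, tt = clustered_sim
        cfg = ClusterConfig(n_pcs_compute=min(30, len(hvg) - 1), n_pcs_use=20)
        _, labels = embed_and_cluster(norm, hvg, cfg)
        assert len(np.unique(labels)) == 3
        assert adjusted_rand_score(tt, labels) > 0.95

    def test_fixed_seed_reproducible(self, clustered_sim):
        norm, hvg, _ = clustered_sim
        cfg = ClusterConfig(n_pcs_compute=min(30, len(hvg) - 1), n_pcs_use=20)
        _, l1 = embed_and_cluster(norm, hvg, cfg)
        _, l2 = embed_and_cluster(norm, hvg, cfg)
        assert np.array_equal(l1, l2)

    def test_stable_under_cell_duplication(self, clustered_sim):
        norm, hvg, _ = clustered_sim
        cfg = ClusterConfig(n_pcs_compute=min(30, len(hvg) - 1), n_pcs_use=20)
        _, base = embed_and_cluster(norm, hvg, cfg)
        import anndata as ad

        doubled = ad.concat([norm, norm], index_unique="-")
        doubled.var = norm.var.copy()
        _, dup = embed_and_cluster(doubled, hvg, cfg)
        assert adjusted_rand_score(np.tile(base, 2), dup) > 0.95

    def test_labels_ordered_by_cluster_size(self, clustered_sim):
        norm, hvg, _ = clustered_sim
        cfg = ClusterConfig(n_pcs_compute=min(30, len(hvg) - 1), n_pcs_use=20)
        _, labels = embed_and_cluster(norm, hvg, cfg)
        sizes = pd.Series(labels).value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_too_few_cells_for_knn_rejected(self, clustered_sim):
        norm, hvg, _ = clustered_sim
        small = norm[:10].copy()
        cfg = ClusterConfig(n_pcs_compute=5, n_pcs_use=5, knn_k=20)
        with pytest.raises(ValueError, match="knn_k"):
            embed_and_cluster(small, hvg[:5], cfg)


def _exact_wilcoxon_by_enumeration(x, y):
    """Full rank-permutation two-sided p for small tie-free samples."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    nx = len(x)
    obs = ranks[:nx].sum() - nx * (nx + 1) / 2  # observed U for x
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        us.append(ranks[list(combo)].sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p_le = (us <= obs).mean()
    p_ge = (us >= obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestFindMarkers:
    def test_wilcoxon_matches_exhaustive_rank_permutation(self):
        rng = np.random.default_rng(3)
        for _ in range(12):
            x = rng.choice(np.arange(1, 40), size=4, replace=False).astype(float)
            y = rng.choice(np.arange(40, 80), size=4, replace=False).astype(float)
            rng.shuffle(y)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                _exact_wilcoxon_by_enumeration(x, y), abs=1e-12
            )

    def test_constant_gene_is_not_a_marker(self):
        X = np.ones((40, 30), dtype=int) * 2
        X[:20, 1] = 9  # one real marker so the frame is nonempty
        norm = _norm_from_dense(X)
        degs = find_markers(norm, np.repeat([0, 1], 20))
        assert not ((degs["gene"] == "E0") & degs["is_marker"]).any()

    def test_exclusive_gene_is_marker_with_positive_lfc(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(2, size=(60, 40))
        X[:30, 0] = rng.poisson(25, size=30)
        X[30:, 0] = 0
        norm = _norm_from_dense(X)
        degs = find_markers(norm, np.repeat([0, 1], 30))
        row = degs[(degs["gene"] == "E0") & (degs["cluster"] == 0)].iloc[0]
        assert row["log_fold_change"] > 0
        assert row["is_marker"]

    def test_multiple_testing_invariants(self, clustered_sim):
        norm, hvg, tt = clustered_sim
        labels = tt.map({"GMC": 0, "tumor": 1, "immune": 2}).to_numpy()
        degs = find_markers(norm, labels)
        tested = degs[~degs["skipped"]]
        assert (tested["p_bonferroni"] >= tested["p_raw"] - 1e-15).all()
        assert (tested["fdr"] >= tested["p_raw"] - 1e-15).all()
        m = norm.n_vars
        np.testing.assert_allclose(
            tested["p_bonferroni"], np.minimum(tested["p_raw"] * m, 1.0)
        )
        assert tested["fraction_in"].between(0, 1).all()

    def test_singleton_cluster_skipped(self):
        X = np.random.default_rng(5).poisson(3, size=(21, 30))
        norm = _norm_from_dense(X)
        labels = np.array([0] * 20 + [1])
        degs = find_markers(norm, labels)
        assert (degs.loc[degs["cluster"] == 1, "skipped"]).all()


class TestAssignCellTypes:
    def test_tumor_marker_cluster_labeled_tumor(self, marker_table):
        tumor_markers = ["EPCAM", "CDH17", "COL3A1", "PDGFRB"]
        other = [f"G{i}" for i in range(26)]
        symbols = tumor_markers + other
        rng = np.random.default_rng(6)
        X = rng.poisson(2, size=(60, 30))
        X[:30, :4] += 20
        norm = _norm_from_dense(X, symbols=symbols)
        assignment, _ = assign_cell_types(norm, np.repeat([0, 1], 30), marker_table)
        assert assignment[0] == "tumor"

    def test_zero_marker_expression_is_unassigned(self, marker_table):
        X = np.ones((20, 30), dtype=int)
        norm = _norm_from_dense(X)  # no marker symbols at all
        assignment, _ = assign_cell_types(norm, np.zeros(20, int), marker_table)
        assert assignment[0] == "unassigned"

    def test_synthetic_types_assigned_perfectly(self, clustered_sim, marker_table):
        norm, _, tt = clustered_sim
        labels = tt.map({"GMC": 0, "tumor": 1, "immune": 2}).to_numpy()
        assignment, scores = assign_cell_types(norm, labels, marker_table)
        assert assignment == {0: "GMC", 1: "tumor", 2: "immune"}


class TestCompositionTests:
    def _annotations(self, rng, shift=1.0, n_samples=12, cells=200):
        rows = []
        for g, p_tumor in (("A", 0.1), ("B", 0.1 * shift)):
            for s in range(n_samples):
                n_tumor = rng.binomial(cells, p_tumor)
                rows += [{"sample": f"{g}{s}", "group": g, "cell_type": "tumor"}] * n_tumor
                rows += [{"sample": f"{g}{s}", "group": g, "cell_type": "GMC"}] * (cells - n_tumor)
        return pd.DataFrame(rows)

    def test_identical_frequencies_give_p_one(self):
        rows = []
        for g in ("A", "B"):
            for s in range(3):
                rows += [{"sample": f"{g}{s}", "group": g, "cell_type": "tumor"}] * 10
                rows += [{"sample": f"{g}{s}", "group": g, "cell_type": "GMC"}] * 30
        res = celltype_frequency_test(pd.DataFrame(rows))
        assert (res["p"] == 1.0).all()
        assert np.allclose(res["mean_a"], res["mean_b"])

    def test_planted_threefold_shift_detected_with_high_power(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            res = celltype_frequency_test(self._annotations(rng, shift=3.0))
            p = res.loc[res["cell_type"] == "tumor", "p"].iloc[0]
            hits += p < 0.05
        assert hits >= 18  # power > 0.9

    def test_per_sample_frequencies_sum_to_one(self):
        rng = np.random.default_rng(8)
        ann = self._annotations(rng)
        freq = (ann.groupby(["sample", "cell_type"]).size().unstack(fill_value=0))
        freq = freq.div(freq.sum(axis=1), axis=0)
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)

    def test_small_group_skipped_with_notice(self):
        rows = [{"sample": "A0", "group": "A", "cell_type": "tumor"}] * 5
        rows += [{"sample": "B0", "group": "B", "cell_type": "tumor"}] * 5
        rows += [{"sample": "B1", "group": "B", "cell_type": "tumor"}] * 5
        res = celltype_frequency_test(pd.DataFrame(rows))
        assert (res["note"] != "").all()

    def test_cluster_composition_proportion_test(self):
        rng = np.random.default_rng(9)
        ann = pd.DataFrame({
            "cluster": np.r_[np.zeros(300, int), np.ones(300, int)],
            "group": np.r_[
                rng.choice(["A", "B"], 300, p=[0.8, 0.2]),
                rng.choice(["A", "B"], 300, p=[0.5, 0.5]),
            ],
        })
        res = cluster_composition_test(ann).set_index("cluster")
        assert res.loc[0, "p"] < 0.05  # skewed cluster detected
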