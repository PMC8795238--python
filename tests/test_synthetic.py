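"""Generator correctness: determinism, planted truth, and count marginals."""

import numpy as np
import pandas as pd
import pytest

from gcatlas import synthetic
from gcatlas.synthetic import (
    BatchSpec,
    BulkConfig,
    GroupSpec,
    IHCConfig,
    RegionSpec,
    SimConfig,
    SimConfigError,
)

from conftest import brute_force_qc, three_type_config


class TestSimulateCells:
    def test_clean_config_produces_cells_that_pass_all_qc_rules(self, three_type_sim):
        cfg, adata, truth = three_type_sim
        assert adata.n_obs == 150
        dense = np.asarray(adata.X.todense())
        special = (adata.var["mito"] | adata.var["hemoglobin"]).to_numpy()
        brute = brute_force_qc(dense, special)
        assert not brute.any(axis=None), "clean cells must pass every rule"

    def test_same_seed_gives_byte_identical_matrices(self):
        a1, t1 = synthetic.simulate_cells(three_type_config())
        a2, t2 = synthetic.simulate_cells(three_type_config())
        assert (a1.X != a2.X).nnz == 0
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.qc_fail, t2.qc_fail)

    def test_planted_low_umi_cells_are_exactly_the_umi_rule_failures(self):
        cfg = three_type_config(violations={"low_umi": 5})
        adata, truth = synthetic.simulate_cells(cfg)
        fails = truth.qc_fail["umi_range"]
        assert fails.sum() == 5
        assert (truth.cells.loc[fails[fails].index, "true_type"] == "lowq_low_umi").all()

    def test_each_planted_violation_kind_fires_its_rule(self):
        cfg = three_type_config(violations={k: 3 for k in synthetic.QC_VIOLATION_KINDS})
        adata, truth = synthetic.simulate_cells(cfg)
        rule_of = {
            "low_umi": "umi_range", "high_umi": "umi_range", "low_sd": "low_sd",
            "high_zero": "high_zero_fraction", "mito_hb": "mito_hb_fraction",
        }
        for kind, rule in rule_of.items():
            planted = truth.cells.index[truth.cells["true_type"] == f"lowq_{kind}"]
            assert truth.qc_fail.loc[planted, rule].all(), kind

    def test_type_means_converge_to_program(self, marker_table):
        # law of large numbers: per-gene mean within 3 SE of the program
        feats = synthetic.default_universe(n_genes=300, seed=3)
        progs = synthetic.default_programs(feats, marker_table, seed=3)
        cfg = SimConfig(features=feats, programs=progs,
                        n_cells_per_type={"GMC": 2000}, libsize_sigma=0.0, seed=3)
        adata, _ = synthetic.simulate_cells(cfg)
        X = np.asarray(adata.X.todense())
        mu = progs["GMC"].to_numpy()
        var = mu + mu**2 / cfg.dispersion
        se = np.sqrt(var / 2000)
        dev = np.abs(X.mean(axis=0) - mu)
        assert (dev <= 3 * np.maximum(se, 1e-9)).mean() > 0.99

    def test_lineage_cells_carry_latent_time_others_do_not(self, lineage_sim):
        _, adata, truth = lineage_sim
        lin = truth.cells["latent_time"].notna()
        assert lin.sum() == 300
        assert truth.cells.loc[lin, "latent_time"].between(0, 1).all()

    def test_cnv_block_raises_mean_in_carrier_cells(self, marker_table):
        feats = synthetic.default_universe(n_genes=400, seed=5, n_chromosomes=4)
        progs = synthetic.default_programs(feats, marker_table, seed=5)
        block = synthetic.CNVBlock("amp", "chr1", 0, 50, 3.0, ("tumor",))
        cfg = SimConfig(features=feats, programs=progs,
                        n_cells_per_type={"tumor": 300, "GMC": 300},
                        cnv_blocks=[block], libsize_sigma=0.0, seed=5)
        adata, truth = synthetic.simulate_cells(cfg)
        cols = synthetic._block_gene_indices(feats, block)
        X = np.asarray(adata.X.todense())
        tumor = (truth.cells["true_type"] == "tumor").to_numpy()
        ratio = X[tumor][:, cols].mean() / X[~tumor][:, cols].mean()
        assert 2.5 < ratio < 3.5
        assert truth.cnv["amp"].to_numpy().sum() == 300

    @pytest.mark.parametrize(
        "mutator",
        [
            lambda c: setattr(c, "programs", c.programs.iloc[0:0]),
            lambda c: c.marker_assignments.update({"GMC": ["NOT_A_GENE"]}),
            lambda c: setattr(c, "lineage", [("GMC", 0.9), ("tumor", 0.1)]),
            lambda c: setattr(c, "n_cells_per_type", {"GMC": -1}),
        ],
        ids=["empty-programs", "unknown-marker", "unsorted-lineage", "negative-count"],
    )
    def test_invalid_configs_rejected(self, mutator):
        cfg = three_type_config()
        mutator(cfg)
        with pytest.raises(SimConfigError):
            synthetic.simulate_cells(cfg)


class TestAlleleCounts:
    def _config_with_variant(self, frac=1.0, vaf=1.0, depth=20.0):
        cfg = three_type_config()
        cfg.mutations = [synthetic.MutationSpec(
            "CCND1_T286", "CCND1", 100, "T286", ("tumor",),
            carrier_fraction=frac, vaf=vaf, mean_depth=depth,
        )]
        return cfg

    def test_full_carriers_at_high_depth_have_alt_reads_and_vaf_near_one(self):
        cfg = self._config_with_variant(frac=1.0, vaf=1.0, depth=20.0)
        adata, truth = synthetic.simulate_cells(cfg)
        ac = synthetic.simulate_allele_counts(truth, cfg)
        carriers = set(truth.carriers.index[truth.carriers["CCND1_T286"]])
        assert carriers == set(truth.cells.index[truth.cells["true_type"] == "tumor"])
        covered = ac[ac["cell_id"].isin(carriers)]
        assert (covered["alt"] + covered["ref"] > 0).all()
        assert (covered["alt"] > 0).all()
        vaf = covered["alt"] / (covered["alt"] + covered["ref"])
        assert vaf.mean() == pytest.approx(1.0, abs=1e-9)

    def test_non_carriers_have_zero_alt(self):
        cfg = self._config_with_variant(frac=1.0, vaf=0.5)
        adata, truth = synthetic.simulate_cells(cfg)
        ac = synthetic.simulate_allele_counts(truth, cfg)
        carriers = set(truth.carriers.index[truth.carriers["CCND1_T286"]])
        noncarrier = ac[~ac["cell_id"].isin(carriers)]
        assert len(noncarrier) > 0
        assert (noncarrier["alt"] == 0).all()

    def test_zero_depth_produces_no_rows(self):
        cfg = self._config_with_variant(depth=0.0)
        adata, truth = synthetic.simulate_cells(cfg)
        ac = synthetic.simulate_allele_counts(truth, cfg)
        assert ac.empty

    def test_expected_vaf_matches_configured_fraction(self):
        cfg = self._config_with_variant(frac=1.0, vaf=0.3, depth=30.0)
        adata, truth = synthetic.simulate_cells(cfg)
        ac = synthetic.simulate_allele_counts(truth, cfg)
        carriers = set(truth.carriers.index[truth.carriers["CCND1_T286"]])
        cov = ac[ac["cell_id"].isin(carriers)]
        pooled = cov["alt"].sum() / (cov["alt"] + cov["ref"]).sum()
        n_reads = (cov["alt"] + cov["ref"]).sum()
        se = np.sqrt(0.3 * 0.7 / n_reads)
        assert abs(pooled - 0.3) < 4 * se


class TestBulkCohort:
    def _sig(self):
        return synthetic.default_signature_matrix()

    def test_event_rate_ratio_recovers_hazard_ratio(self):
        cfg = BulkConfig(
            signature=self._sig(),
            groups={"hi": GroupSpec(2000, 0.02, {"EMT": 1.0}),
                    "lo": GroupSpec(2000, 0.01, {"MSI": 1.0})},
            censor_rate=0.0, seed=4,
        )
        expr, meta = synthetic.simulate_bulk_cohort(cfg)
        rate = {g: meta.loc[meta["group"] == g, "event"].sum()
                / meta.loc[meta["group"] == g, "time"].sum() for g in ("hi", "lo")}
        assert rate["hi"] / rate["lo"] == pytest.approx(2.0, rel=0.1)

    def test_single_batch_zero_shift_is_mixture_plus_noise(self):
        sig = self._sig()
        cfg = BulkConfig(
            signature=sig, groups={"g": GroupSpec(200, 0.01, {"EMT": 1.0})},
            batches=[BatchSpec("b0", 0.0, 1.0)], concentration=1e7,
            noise_sigma=0.05, seed=4,
        )
        expr, meta = synthetic.simulate_bulk_cohort(cfg)
        resid = expr.to_numpy() - sig["EMT"].to_numpy()
        assert np.abs(resid.mean()) < 0.02
        assert np.abs(resid).max() < 0.05 * 6

    def test_full_censoring_means_no_events(self):
        cfg = BulkConfig(
            signature=self._sig(), groups={"g": GroupSpec(50, 0.01, {"EMT": 1.0})},
            censor_rate=1.0, seed=4,
        )
        _, meta = synthetic.simulate_bulk_cohort(cfg)
        assert (meta["event"] == 0).all()

    def test_nonpositive_hazard_rejected(self):
        cfg = BulkConfig(
            signature=self._sig(), groups={"g": GroupSpec(10, 0.0, {"EMT": 1.0})},
        )
        with pytest.raises(SimConfigError):
            synthetic.simulate_bulk_cohort(cfg)

    def test_determinism(self):
        cfg = synthetic.default_bulk_config(seed=9, n_per_group=30)
        e1, m1 = synthetic.simulate_bulk_cohort(cfg)
        e2, m2 = synthetic.simulate_bulk_cohort(synthetic.default_bulk_config(seed=9, n_per_group=30))
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(m1, m2)


class TestIHCSim:
    def test_no_regions_gives_all_negative_truth(self):
        cfg = IHCConfig(width=100, height=100, n_cols=10, n_rows=10,
                        channels=("A",), seed=1)
        channels, truth = synthetic.simulate_ihc(cfg)
        assert not truth.tile_positive["A"].any()

    def test_region_covering_four_tiles_yields_copositive_count_four(self):
        cfg = IHCConfig(width=100, height=100, n_cols=10, n_rows=10,
                        channels=("A", "B"),
                        regions=[RegionSpec(10, 10, 30, 30, ("A", "B"))], seed=1)
        _, truth = synthetic.simulate_ihc(cfg)
        assert truth.co_positive("A", "B").sum() == 4

    def test_same_seed_gives_identical_images(self):
        cfg = IHCConfig(seed=5, regions=[RegionSpec(0, 0, 50, 50, ("MRTFA",))])
        c1, _ = synthetic.simulate_ihc(cfg)
        c2, _ = synthetic.simulate_ihc(cfg)
        for ch in c1:
            assert np.array_equal(c1[ch], c2[ch])

    def test_out_of_bounds_region_rejected(self):
        cfg = IHCConfig(width=100, height=100, n_cols=10, n_rows=10,
                        channels=("A",), regions=[RegionSpec(50, 50, 150, 80, ("A",))])
        with pytest.raises(SimConfigError):
            synthetic.simulate_ihc(cfg)

    def test_indivisible_grid_rejected(self):
        with pytest.raises(SimConfigError):
            synthetic.simulate_ihc(IHCConfig(width=101, height=100, n_cols=10, n_rows=10))
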