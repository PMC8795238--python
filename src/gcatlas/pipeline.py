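"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (simulate -> qc -> annotate -> {cnv,
trajectory, mutations, signatures} -> cohort -> ihc), each gated by a
toggle.  A manifest records the package version, seed, per-stage row counts
and a config hash; rerunning the same config reproduces identical manifest
counts.  A failed stage halts the run with the stage name, leaving prior
outputs in place and a ``<stage>.partial`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import annotate as ann_mod
from . import cnv as cnv_mod
from . import ihc as ihc_mod
from . import io as gio
from . import mutations as mut_mod
from . import preprocess, signatures, survival, synthetic, trajectory

log = logging.getLogger("gcatlas")

DEFAULT_STAGES = (
    "simulate", "qc", "annotate", "cnv", "trajectory",
    "mutations", "signatures", "cohort", "ihc",
)


@dataclass
class PipelineConfig:
    outdir: str = "gcatlas_run"
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    cells_per_type: int = 60
    n_lineage_cells: int = 300
    n_genes: int = 1000
    scale_factor: float = 10_000
    resolution: float = 0.8
    n_states: int = 3
    exclude_types: tuple[str, ...] = ("fibroblast", "EC")
    n_bulk_per_group: int = 120
    horizon: float | None = 60.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "exclude_types" in raw:
            raw["exclude_types"] = tuple(raw["exclude_types"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    state: dict = {}
    for stage in DEFAULT_STAGES:
        if stage not in config.stages:
            continue
        marker = out / f"{stage}.partial"
        marker.touch()
        log.info("stage %s", stage)
        try:
            counts = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:  # halt with stage name, keep partial marker
            raise StageError(stage, exc) from exc
        marker.unlink(missing_ok=True)
        manifest["stages"][stage] = counts
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=int)
    return manifest


def _stage_simulate(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    sim = synthetic.default_atlas_config(
        seed=cfg.seed, cells_per_type=cfg.cells_per_type,
        n_lineage_cells=cfg.n_lineage_cells, n_genes=cfg.n_genes,
    )
    adata, truth = synthetic.simulate_cells(sim)
    st["sim"], st["counts"], st["truth"] = sim, adata, truth
    gio.write_10x_dir(adata, out / "sim_counts")
    gio.write_tsv(truth.cells, out / "truth_cells.tsv", index=True)
    return {"n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars)}


def _stage_qc(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    kept, report = preprocess.filter_cells(st["counts"])
    norm = preprocess.normalize_log(kept, cfg.scale_factor)
    st["norm"] = norm
    gio.write_tsv(report, out / "qc_report.tsv")
    pd.Series(kept.obs_names).to_csv(out / "kept_barcodes.tsv", sep="\t",
                                     index=False, header=False)
    return {"n_kept": int(kept.n_obs), "n_removed": int(len(report))}


def _stage_annotate(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    norm = st["norm"]
    hvg = ann_mod.select_hvg(norm)
    n_pcs = min(30, max(2, len(hvg) - 1))
    ccfg = ann_mod.ClusterConfig(
        n_pcs_compute=n_pcs, n_pcs_use=min(20, n_pcs),
        resolution=cfg.resolution, seed=12345,
    )
    emb, clusters = ann_mod.embed_and_cluster(norm, hvg, ccfg)
    compartment = preprocess.split_immune(norm, clusters)
    marker_table = gio.read_marker_table(gio.packaged_data("markers.tsv"))
    assignment, scores = ann_mod.assign_cell_types(norm, clusters, marker_table)
    obs = pd.DataFrame(
        {
            "cluster": clusters,
            "compartment": compartment.to_numpy(),
            "cell_type": [assignment[c] for c in clusters],
        },
        index=norm.obs_names,
    )
    st.update(hvg=hvg, clusters=clusters, annotations=obs)
    gio.write_tsv(obs, out / "annotations.tsv", index=True)
    return {"n_hvg": len(hvg), "n_clusters": int(len(np.unique(clusters))),
            "n_immune": int((obs["compartment"] == "immune").sum())}


def _stage_cnv(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    obs = st["annotations"]
    reference = obs.index[obs["cell_type"].isin(
        ["GMC", "PMC", "fibroblast", "EC", "enteroendocrine"]
    )]
    if len(reference) == 0:
        reference = obs.index[:50]
    cnv = cnv_mod.infer_cnv_scores(st["norm"], list(reference), window=31)
    calls = cnv_mod.call_gene_cnv(
        cnv, ["CD44", "CDK6", "GATA4", "GATA6", "KLF5", "KRAS", "ARID1A", "SMAD4"],
        obs["cell_type"].to_numpy(),
    )
    st["cnv"] = cnv
    gio.write_tsv(cnv.burden.to_frame(), out / "cnv_burden.tsv", index=True)
    gio.write_tsv(calls, out / "cnv_calls.tsv")
    return {"n_scored": int(cnv.values.shape[0]),
            "n_amp_calls": int((calls["call"] == "amp").sum())}


def _stage_trajectory(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    norm, obs = st["norm"], st["annotations"]
    non_immune = obs["compartment"] != "immune"
    sub = norm[non_immune.to_numpy()].copy()
    ann = obs.loc[non_immune, "cell_type"]
    hvg = [g for g in st["hvg"] if g in sub.var_names]
    traj = trajectory.build_trajectory(
        sub, hvg, root_rule=["GMC", "enteroendocrine"], annotations=ann,
        n_medoids=min(50, sub.n_obs // 4), seed=12345,
    )
    states = trajectory.assign_progression_states(
        traj, ann, n_states=cfg.n_states, exclude_types=list(cfg.exclude_types)
    )
    st["trajectory"], st["states"] = traj, states
    df = pd.DataFrame({"pseudotime": traj.pseudotime, "branch": traj.branch_state,
                       "state": states})
    gio.write_tsv(df, out / "trajectory.tsv", index=True)
    (out / "trajectory_tree.nwk").write_text(traj.to_newick() + "\n")
    return {"n_cells": int(sub.n_obs),
            "n_states": int(states[~states.str.startswith("excluded")].nunique())}


def _stage_mutations(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    ac = synthetic.simulate_allele_counts(st["truth"], st["sim"])
    catalog = mut_mod.load_catalog()
    obs = st["annotations"]
    kept_ac = ac[ac["cell_id"].isin(obs.index)]
    filtered = mut_mod.filter_hotspot_variants(kept_ac, catalog, obs["compartment"])
    vaf = mut_mod.tabulate_vaf(filtered)
    table = mut_mod.mutation_by_celltype(filtered, obs["cell_type"], catalog)
    st["vaf"] = vaf
    gio.write_tsv(vaf, out / "vaf.tsv")
    gio.write_tsv(table, out / "mutations_by_celltype.tsv")
    return {"n_variants": int(filtered["variant_id"].nunique()),
            "n_mutated_cells": int(vaf.loc[vaf["mutated"], "cell_id"].nunique())}


def _stage_signatures(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    norm, obs = st["norm"], st["annotations"]
    tumor = obs.index[obs["cell_type"] == "tumor"]
    target = norm[norm.obs_names.isin(tumor)].copy() if len(tumor) >= 10 else norm
    sets = gio.read_gmt(gio.packaged_data("gene_sets.gmt"))
    scores = pd.DataFrame({
        "intestinal": signatures.score_gene_set(
            target, signatures.GeneSet("intestinal", tuple(sets["intestinal"]))),
        "EMT": signatures.score_gene_set(
            target, signatures.GeneSet("EMT", tuple(sets["EMT"]))),
        "EmyoT": signatures.score_gene_set(
            target, signatures.GeneSet("EmyoT", tuple(sets["EmyoT"]))),
    })
    groups = signatures.classify_tumor_groups(scores)
    sig = synthetic.default_signature_matrix()
    decon = signatures.deconvolve_subtypes(target, sig)
    st["tumor_groups"] = groups
    gio.write_tsv(groups, out / "tumor_groups.tsv", index=True)
    gio.write_tsv(decon, out / "subtype_weights.tsv", index=True)
    return {"n_scored": int(len(groups)),
            **{g: int((groups["label"] == g).sum()) for g in signatures.TUMOR_GROUPS}}


def _stage_cohort(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    bcfg = synthetic.default_bulk_config(seed=cfg.seed, n_per_group=cfg.n_bulk_per_group)
    expr, meta = synthetic.simulate_bulk_cohort(bcfg)
    cohorts = [
        survival.BulkCohort(expr.loc[meta["batch"] == b], meta.loc[meta["batch"] == b])
        for b in meta["batch"].unique()
    ]
    merged = survival.harmonize_batches(cohorts)
    res = survival.fit_cox_km(merged.meta, reference="intestinal", horizon=cfg.horizon)
    sets = gio.read_gmt(gio.packaged_data("gene_sets.gmt"))
    icaf = signatures.score_gene_set(merged.expr,
                                     signatures.GeneSet("iCAF", tuple(sets["iCAF"])))
    stem = signatures.score_gene_set(merged.expr,
                                     signatures.GeneSet("stemness", tuple(sets["stemness"])))
    assoc = survival.associate_scores(icaf, stem)
    st["cohort"], st["cox"] = merged, res
    gio.write_tsv(res.hazard_ratios.reset_index(), out / "hazard_ratios.tsv")
    return {"n_samples": int(len(merged.meta)),
            "logrank_p": float(res.logrank_p),
            "emyot_hr": float(res.hazard_ratios.loc["EmyoT", "hr"]),
            "icaf_stemness_r": float(assoc.pearson_r)}


def _stage_ihc(cfg: PipelineConfig, st: dict, out: Path) -> dict:
    icfg = synthetic.IHCConfig(
        seed=cfg.seed,
        regions=[
            synthetic.RegionSpec(40, 40, 120, 120, ("MRTFA", "SRF", "IGFBP5")),
            synthetic.RegionSpec(200, 100, 280, 200, ("MRTFA", "SRF")),
            synthetic.RegionSpec(300, 220, 380, 300, ("IGFBP5",)),
        ],
    )
    channels, _ = synthetic.simulate_ihc(icfg)
    grid = ihc_mod.grid_tiles(icfg.width, icfg.height, icfg.n_cols, icfg.n_rows)
    pos = {ch: ihc_mod.annotate_tiles(im, grid, positive_fraction=icfg.positive_fraction)
           for ch, im in channels.items()}
    both, n_double = ihc_mod.overlap_tiles(pos["MRTFA"], pos["SRF"])
    overlay = ihc_mod.render_overlay(channels, grid, both)
    iio.imwrite(out / "ihc_overlay.png", overlay)
    gio.write_tsv(ihc_mod.tile_table(grid, pos), out / "ihc_tiles.tsv")
    return {"n_tiles": grid.n_tiles, "n_double_positive_mrtfa_srf": n_double}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "annotate": _stage_annotate,
    "cnv": _stage_cnv,
    "trajectory": _stage_trajectory,
    "mutations": _stage_mutations,
    "signatures": _stage_signatures,
    "cohort": _stage_cohort,
    "ihc": _stage_ihc,
}
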