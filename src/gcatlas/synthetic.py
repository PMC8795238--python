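"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of a droplet scRNA-seq gastric atlas and
its companion assays:

* UMI counts are negative-binomial (gamma–Poisson) around cell-type-specific
  mean programs with elevated marker genes, with log-normal per-cell library
  size variation;
* a continuous differentiation lineage is produced by piecewise-linear
  interpolation between anchor programs at a latent time in [0, 1];
* copy-number events multiply the mean of contiguous genomic gene blocks in
  carrier cell types;
* low-quality droplets violating each QC rule are planted explicitly;
* hotspot variants yield per-cell ref/alt allele counts with Poisson depth
  and binomial alt reads in carrier cells;
* bulk cohorts are convex mixtures of reference profiles with batch
  location/scale shifts and group-dependent exponential survival;
* stain channels are images with planted high-intensity regions whose
  tile-level positivity is recorded exactly.

Everything is deterministic given (config, seed), and every planted event is
recoverable from :class:`SimTruth` by direct lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as gio
from .preprocess import QCConfig, evaluate_qc_rules

QC_VIOLATION_KINDS = ("low_sd", "high_zero", "mito_hb", "low_umi", "high_umi")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CNVBlock:
    """A contiguous copy-number event: ``n_genes`` genes on ``chromosome``
    starting at within-chromosome gene index ``start_index``, with mean
    expression multiplied by ``multiplier`` in ``carrier_types``."""

    block_id: str
    chromosome: str
    start_index: int
    n_genes: int
    multiplier: float
    carrier_types: tuple[str, ...]


@dataclass(frozen=True)
class MutationSpec:
    """A planted hotspot variant carried by a fraction of some cell types."""

    variant_id: str
    gene: str
    position: int
    protein_change: str
    carrier_types: tuple[str, ...]
    carrier_fraction: float = 1.0
    vaf: float = 1.0
    mean_depth: float = 10.0


@dataclass
class SimConfig:
    """Full specification of a simulated single-cell experiment."""

    features: pd.DataFrame  # gene_id, symbol, chromosome, start
    programs: pd.DataFrame  # genes x cell types, mean expression
    n_cells_per_type: dict[str, int]
    marker_assignments: dict[str, list[str]] = field(default_factory=dict)
    lineage: list[tuple[str, float]] = field(default_factory=list)
    n_lineage_cells: int = 0
    qc_violations: dict[str, int] = field(default_factory=dict)
    cnv_blocks: list[CNVBlock] = field(default_factory=list)
    mutations: list[MutationSpec] = field(default_factory=list)
    dispersion: float = 2.0
    libsize_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.programs.empty or self.programs.shape[0] == 0:
            raise SimConfigError("empty program matrix")
        if not self.n_cells_per_type:
            raise SimConfigError("at least one cell type required")
        if (self.programs.to_numpy() < 0).any():
            raise SimConfigError("program means must be non-negative")
        for t, n in self.n_cells_per_type.items():
            if n < 0:
                raise SimConfigError(f"negative cell count for {t}")
            if t not in self.programs.columns:
                raise SimConfigError(f"no program for cell type {t!r}")
            if not np.any(self.programs[t].to_numpy() > 0):
                raise SimConfigError(f"empty program vector for {t!r}")
        symbols = set(self.features["symbol"])
        for t, markers in self.marker_assignments.items():
            for m in markers:
                if m not in symbols:
                    raise SimConfigError(f"marker {m!r} absent from gene universe")
        times = [u for _, u in self.lineage]
        if times and (min(times) < 0 or max(times) > 1 or sorted(times) != times):
            raise SimConfigError("lineage latent times must be sorted in [0, 1]")
        for t, _ in self.lineage:
            if t not in self.programs.columns:
                raise SimConfigError(f"lineage anchor {t!r} has no program")
        for k, n in self.qc_violations.items():
            if k not in QC_VIOLATION_KINDS:
                raise SimConfigError(f"unknown QC violation kind {k!r}")
            if n < 0:
                raise SimConfigError("violation counts must be >= 0")
        for b in self.cnv_blocks:
            if b.multiplier <= 0:
                raise SimConfigError("CNV multiplier must be > 0")
            chrom_genes = (self.features["chromosome"] == b.chromosome).sum()
            if b.start_index < 0 or b.start_index + b.n_genes > chrom_genes:
                raise SimConfigError(f"CNV block {b.block_id} outside chromosome")
        for m in self.mutations:
            if not 0 <= m.carrier_fraction <= 1 or not 0 <= m.vaf <= 1:
                raise SimConfigError("carrier fraction and VAF must lie in [0, 1]")
            if m.gene not in symbols:
                raise SimConfigError(f"variant gene {m.gene!r} absent from gene universe")


@dataclass
class SimTruth:
    """Planted ground truth: one row per simulated cell in ``cells``
    (true_type, latent_time, stage), boolean rule table ``qc_fail``
    (cells x QC rules), ``cnv`` (cells x blocks) and ``carriers``
    (cells x variants)."""

    cells: pd.DataFrame
    qc_fail: pd.DataFrame
    cnv: pd.DataFrame
    carriers: pd.DataFrame

    @property
    def lineage_cells(self) -> pd.Index:
        return self.cells.index[self.cells["latent_time"].notna()]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw: var = mu + mu^2 / dispersion."""
    mean = np.maximum(mean, 0)
    lam = np.where(mean > 0, rng.gamma(dispersion, 1.0, size=mean.shape) * mean / dispersion, 0.0)
    return rng.poisson(lam)


def _genome_order(features: pd.DataFrame) -> pd.DataFrame:
    return features.sort_values(["chromosome", "start", "gene_id"], kind="stable")


def _block_gene_indices(features: pd.DataFrame, block: CNVBlock) -> np.ndarray:
    """Positional indices (in feature-table order) of a block's genes."""
    ordered = _genome_order(features.reset_index(drop=True).reset_index())
    on_chrom = ordered[ordered["chromosome"] == block.chromosome]
    return on_chrom["index"].to_numpy()[block.start_index : block.start_index + block.n_genes]


def simulate_cells(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Draw the UMI count matrix and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    features = config.features.reset_index(drop=True)
    n_genes = len(features)
    base = config.programs.to_numpy().T  # types x genes
    type_names = list(config.programs.columns)
    type_idx = {t: i for i, t in enumerate(type_names)}

    block_cols: dict[str, np.ndarray] = {
        b.block_id: _block_gene_indices(features, b) for b in config.cnv_blocks
    }

    rows: list[np.ndarray] = []
    meta: list[dict] = []

    def type_mean(t: str) -> np.ndarray:
        mu = base[type_idx[t]].copy()
        for b in config.cnv_blocks:
            if t in b.carrier_types:
                mu[block_cols[b.block_id]] *= b.multiplier
        return mu

    for t, n in config.n_cells_per_type.items():
        mu = type_mean(t)
        for _ in range(n):
            lib = float(np.exp(rng.normal(0.0, config.libsize_sigma)))
            rows.append(_nb_counts(rng, mu * lib, config.dispersion))
            meta.append({"true_type": t, "latent_time": np.nan, "stage": -1})

    # continuous lineage: convex interpolation of consecutive anchor programs
    if config.lineage and config.n_lineage_cells:
        anchors = [(t, u) for t, u in config.lineage]
        times = np.sort(rng.uniform(0, 1, size=config.n_lineage_cells))
        anchor_u = np.array([u for _, u in anchors])
        for u in times:
            k = int(np.clip(np.searchsorted(anchor_u, u) - 1, 0, len(anchors) - 2))
            t0, u0 = anchors[k]
            t1, u1 = anchors[k + 1]
            w = 0.0 if u1 == u0 else (u - u0) / (u1 - u0)
            nearest = t1 if w > 0.5 else t0
            mu = (1 - w) * type_mean(t0) + w * type_mean(t1)
            lib = float(np.exp(rng.normal(0.0, config.libsize_sigma)))
            rows.append(_nb_counts(rng, mu * lib, config.dispersion))
            # planted stage = equal-width latent-time phase (one per anchor)
            stage = min(int(u * len(anchors)), len(anchors) - 1)
            meta.append({"true_type": nearest, "latent_time": float(u), "stage": stage})

    # planted low-quality droplets
    baseline = base.mean(axis=0)
    baseline = baseline / baseline.sum()
    special = gio.flag_special_genes(features)
    special_mask = (special["mito"] | special["hemoglobin"]).to_numpy()
    for kind, count in config.qc_violations.items():
        for _ in range(count):
            if kind == "low_umi":
                counts = rng.multinomial(50, baseline)
            elif kind == "high_umi":
                counts = rng.multinomial(30_000, baseline)
            elif kind == "mito_hb":
                if not special_mask.any():
                    raise SimConfigError("no mito/hemoglobin genes in universe")
                p = np.where(special_mask, 0.5 / special_mask.sum(), 0.0)
                p += 0.5 * np.where(special_mask, 0.0, baseline) / baseline[~special_mask].sum()
                counts = rng.multinomial(1_000, p / p.sum())
            elif kind == "low_sd":
                counts = np.ones(n_genes, dtype=int)
            elif kind == "high_zero":
                m = max(1, int(np.floor(0.08 * n_genes)))
                eligible = np.flatnonzero(~special_mask)
                chosen = rng.choice(eligible, size=min(m, eligible.size), replace=False)
                counts = np.zeros(n_genes, dtype=int)
                counts[chosen] = 17
            rows.append(counts)
            meta.append({"true_type": f"lowq_{kind}", "latent_time": np.nan, "stage": -1})

    X = sp.csr_matrix(np.vstack(rows)) if rows else sp.csr_matrix((0, n_genes))
    barcodes = [f"cell{i:05d}" for i in range(X.shape[0])]
    adata = gio.make_anndata(X, barcodes, features)

    cells = pd.DataFrame(meta, index=pd.Index(barcodes, name="barcode"))
    qc_fail = evaluate_qc_rules(adata, QCConfig())

    cnv = pd.DataFrame(
        {
            b.block_id: cells["true_type"].isin(b.carrier_types).to_numpy()
            for b in config.cnv_blocks
        },
        index=cells.index,
        dtype=bool,
    )

    carrier_cols = {}
    for m in config.mutations:
        eligible = cells["true_type"].isin(m.carrier_types).to_numpy()
        draw = rng.uniform(size=len(cells)) < m.carrier_fraction
        carrier_cols[m.variant_id] = eligible & draw
    carriers = pd.DataFrame(carrier_cols, index=cells.index, dtype=bool)

    truth = SimTruth(cells=cells, qc_fail=qc_fail, cnv=cnv, carriers=carriers)
    adata.obs["true_type"] = cells["true_type"].to_numpy()
    adata.uns["sim_seed"] = int(config.seed)
    return adata, truth


def simulate_allele_counts(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Per-cell ref/alt read counts at each configured variant.

    Depth at a site is Poisson(mean_depth) for every cell; carrier cells draw
    alt reads binomially at the configured VAF; non-carriers get alt = 0.
    Cells with zero depth at a site produce no row (site not covered).
    Returns a tidy DataFrame (cell_id, variant_id, ref, alt).
    """
    rng = np.random.default_rng([config.seed, 7])
    records = []
    for m in config.mutations:
        if m.variant_id not in truth.carriers.columns:
            raise SimConfigError(f"variant {m.variant_id!r} not in truth catalog")
        is_carrier = truth.carriers[m.variant_id].to_numpy()
        depth = rng.poisson(m.mean_depth, size=len(truth.cells))
        alt = np.where(is_carrier, rng.binomial(np.maximum(depth, 0), m.vaf), 0)
        ref = depth - alt
        covered = depth > 0
        for cell, r, a in zip(truth.cells.index[covered], ref[covered], alt[covered]):
            records.append((cell, m.variant_id, int(r), int(a)))
    return pd.DataFrame(records, columns=["cell_id", "variant_id", "ref", "alt"])


# ---------------------------------------------------------------------------
# bulk cohorts with survival


@dataclass(frozen=True)
class GroupSpec:
    """A bulk sample group: size, exponential hazard, and the mixture of
    reference profiles its expression is drawn around."""

    n_samples: int
    hazard: float
    mixture: dict[str, float]


@dataclass(frozen=True)
class BatchSpec:
    name: str
    shift: float = 0.0
    scale: float = 1.0


@dataclass
class BulkConfig:
    signature: pd.DataFrame  # genes x reference components
    groups: dict[str, GroupSpec]
    batches: list[BatchSpec] = field(default_factory=lambda: [BatchSpec("b0")])
    concentration: float = 50.0
    noise_sigma: float = 0.2
    censor_rate: float = 0.0
    stages: list[str] | None = None
    stage_genes: list[str] | None = None
    stage_step: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) < 1:
            raise SimConfigError("at least one group required")
        for name, g in self.groups.items():
            if g.hazard <= 0:
                raise SimConfigError(f"hazard must be > 0 for group {name!r}")
            for c in g.mixture:
                if c not in self.signature.columns:
                    raise SimConfigError(f"mixture component {c!r} not in signature")
        if not self.batches:
            raise SimConfigError("at least one batch required")


def simulate_bulk_cohort(config: BulkConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk expression + survival records.

    Expression per sample is a convex (Dirichlet-jittered) mixture of
    signature columns, shifted per batch (location/scale) with Gaussian
    noise.  Survival times are exponential at the group hazard, with
    independent exponential censoring tuned so a fraction ``censor_rate`` of
    samples is censored (``censor_rate >= 1`` censors everything).
    Returns (expr: samples x genes, meta with batch/group/time/event/stage).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sig = config.signature.to_numpy()
    comp_idx = {c: i for i, c in enumerate(config.signature.columns)}
    expr_rows, meta_rows = [], []
    i = 0
    for gname, g in config.groups.items():
        alpha = np.full(len(comp_idx), 1e-6)
        for c, w in g.mixture.items():
            alpha[comp_idx[c]] += w * config.concentration
        for _ in range(g.n_samples):
            w = rng.dirichlet(alpha)
            x = sig @ w
            batch = config.batches[i % len(config.batches)]
            x = batch.shift + batch.scale * x + rng.normal(0, config.noise_sigma, size=x.shape)
            t_event = rng.exponential(1.0 / g.hazard)
            if config.censor_rate <= 0:
                time, event = t_event, 1
            elif config.censor_rate >= 1:
                time, event = rng.exponential(1.0 / g.hazard), 0
            else:
                c_rate = g.hazard * config.censor_rate / (1 - config.censor_rate)
                t_cens = rng.exponential(1.0 / c_rate)
                time, event = min(t_event, t_cens), int(t_event <= t_cens)
            stage = None
            if config.stages:
                stage = config.stages[i % len(config.stages)]
                if config.stage_genes:
                    gmask = config.signature.index.isin(config.stage_genes)
                    x = x + gmask * config.stage_step * config.stages.index(stage)
            expr_rows.append(x)
            meta_rows.append(
                {"sample": f"s{i:04d}", "batch": batch.name, "group": gname,
                 "time": float(time), "event": int(event), "stage": stage}
            )
            i += 1
    expr = pd.DataFrame(
        np.vstack(expr_rows),
        index=[m["sample"] for m in meta_rows],
        columns=config.signature.index,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return expr, meta


# ---------------------------------------------------------------------------
# stain-channel images


@dataclass(frozen=True)
class RegionSpec:
    """A planted high-intensity rectangle [x0, x1) x [y0, y1) in pixels,
    present in the listed channels."""

    x0: int
    y0: int
    x1: int
    y1: int
    channels: tuple[str, ...]
    intensity: float = 200.0


@dataclass
class IHCConfig:
    width: int = 450
    height: int = 340
    n_cols: int = 45
    n_rows: int = 34
    channels: tuple[str, ...] = ("MRTFA", "SRF", "IGFBP5")
    regions: list[RegionSpec] = field(default_factory=list)
    background: float = 30.0
    noise_sigma: float = 8.0
    positive_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.width % self.n_cols or self.height % self.n_rows:
            raise SimConfigError("image dimensions must divide evenly into the grid")
        for r in self.regions:
            if not (0 <= r.x0 < r.x1 <= self.width and 0 <= r.y0 < r.y1 <= self.height):
                raise SimConfigError(f"region {r} outside image bounds")
            for c in r.channels:
                if c not in self.channels:
                    raise SimConfigError(f"region channel {c!r} unknown")


@dataclass
class IHCTruth:
    """Exact per-tile positivity per channel (n_rows x n_cols boolean arrays)
    and per-pair co-positivity derived from planted geometry."""

    tile_positive: dict[str, np.ndarray]

    def co_positive(self, a: str, b: str) -> np.ndarray:
        return self.tile_positive[a] & self.tile_positive[b]


def simulate_ihc(config: IHCConfig) -> tuple[dict[str, np.ndarray], IHCTruth]:
    """Render stain channels (uint8 H x W) and their exact tile truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    th, tw = config.height // config.n_rows, config.width // config.n_cols
    channels: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}
    for ch in config.channels:
        mask = np.zeros((config.height, config.width), dtype=bool)
        for r in config.regions:
            if ch in r.channels:
                mask[r.y0 : r.y1, r.x0 : r.x1] = True
        img = rng.normal(config.background, config.noise_sigma, size=mask.shape)
        for r in config.regions:
            if ch in r.channels:
                img[r.y0 : r.y1, r.x0 : r.x1] = r.intensity + rng.normal(
                    0, config.noise_sigma, size=(r.y1 - r.y0, r.x1 - r.x0)
                )
        channels[ch] = np.clip(img, 0, 255).astype(np.uint8)
        # exact tile coverage of the planted mask
        frac = mask.reshape(config.n_rows, th, config.n_cols, tw).mean(axis=(1, 3))
        truth[ch] = frac >= config.positive_fraction
    return channels, IHCTruth(tile_positive=truth)


# ---------------------------------------------------------------------------
# default study-like configuration builders

ATLAS_TYPES = (
    "EC", "enteroendocrine", "fibroblast", "GMC", "IM",
    "chief", "goblet", "MSC", "PC", "PMC", "tumor", "immune",
)

_MT_GENES = tuple(f"MT-{g}" for g in (
    "ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND4L", "ND4", "ND5", "ND6", "CYB",
))
_HB_GENES = ("HBA1", "HBA2", "HBB")


def default_universe(n_genes: int = 1000, seed: int = 0, n_chromosomes: int = 22) -> pd.DataFrame:
    """A gene universe containing every bundled marker / gene-set / hotspot /
    CNV-target symbol, mitochondrial and hemoglobin genes, padded with
    background genes, laid out across 22 chromosomes."""
    symbols: list[str] = []
    for m in gio.read_marker_table(gio.packaged_data("markers.tsv")).values():
        symbols.extend(m)
    for genes in gio.read_gmt(gio.packaged_data("gene_sets.gmt")).values():
        symbols.extend(genes)
    symbols.extend(
        pd.read_csv(gio.packaged_data("hotspots_synthetic.tsv"), sep="\t")["gene"]
    )
    symbols.extend(["CD44", "GATA4", "GATA6", "KLF5", "ARID1A", "SMAD4",
                    "MDM2", "CDKN1A", "MLH1", "MSH2", "MSH6"])
    symbols.extend(_MT_GENES + _HB_GENES)
    seen: list[str] = list(dict.fromkeys(symbols))
    n_bg = max(0, n_genes - len(seen))
    seen += [f"BG{i:04d}" for i in range(n_bg)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(seen))
    chroms = [f"chr{(i % n_chromosomes) + 1}" for i in range(len(seen))]
    feats = pd.DataFrame(
        {
            "gene_id": [f"ENSG{i:07d}" for i in range(len(seen))],
            "symbol": [seen[j] for j in order],
            "chromosome": sorted(chroms, key=lambda c: int(c[3:])),
        }
    )
    feats["start"] = feats.groupby("chromosome").cumcount() * 100_000 + 1
    return feats


def default_programs(
    features: pd.DataFrame,
    marker_table: dict[str, list[str]] | None = None,
    base_mean: float = 2.0,
    marker_boost: float = 8.0,
    de_prob: float = 0.1,
    de_sigma: float = 1.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-expression programs per cell type.

    Each type shares a log-normal baseline, elevates its markers, and
    perturbs a random ``de_prob`` fraction of genes by log-normal
    differential-expression factors (the way cell identity programs differ
    in real tissue, where types deviate in many genes beyond their
    canonical markers).  Mito/hemoglobin genes are kept near zero so
    healthy cells pass the contamination rule.
    """
    if marker_table is None:
        marker_table = gio.read_marker_table(gio.packaged_data("markers.tsv"))
    rng = np.random.default_rng(seed)
    baseline = base_mean * rng.lognormal(0, 0.4, size=len(features))
    flags = gio.flag_special_genes(features)
    special = (flags["mito"] | flags["hemoglobin"]).to_numpy()
    baseline[special] = 0.02
    sym_pos = {s: i for i, s in enumerate(features["symbol"])}
    all_markers = {m for ms in marker_table.values() for m in ms}
    eligible = np.flatnonzero(
        ~special & ~features["symbol"].isin(all_markers).to_numpy()
    )
    progs = {}
    for t, markers in marker_table.items():
        mu = baseline.copy()
        n_de = int(round(de_prob * len(eligible)))
        de_genes = rng.choice(eligible, size=n_de, replace=False)
        mu[de_genes] *= np.exp(rng.normal(0, de_sigma, size=n_de))
        for m in markers:
            if m in sym_pos:
                mu[sym_pos[m]] += marker_boost
        progs[t] = mu
    return pd.DataFrame(progs, index=features["gene_id"].to_numpy())


def default_atlas_config(seed: int = 0, cells_per_type: int = 60,
                         n_lineage_cells: int = 300, n_genes: int = 1000) -> SimConfig:
    """A study-shaped default: the ten gastric cell types plus immune cells,
    a GMC -> MSC -> tumor lineage, one amplified block carried by tumor
    cells, CCND1 hotspot carriers confined to the MSC/PC/tumor lineage, and a
    handful of planted QC failures of each kind."""
    features = default_universe(n_genes=n_genes, seed=seed)
    marker_table = gio.read_marker_table(gio.packaged_data("markers.tsv"))
    programs = default_programs(features, marker_table, seed=seed)
    hot = pd.read_csv(gio.packaged_data("hotspots_synthetic.tsv"), sep="\t")

    tumor_chrom = "chr11"
    chrom_size = (features["chromosome"] == tumor_chrom).sum()
    block = CNVBlock(
        block_id="amp_chr11",
        chromosome=tumor_chrom,
        start_index=2,
        n_genes=min(20, chrom_size - 2),
        multiplier=2.0,
        carrier_types=("tumor",),
    )
    muts = [
        MutationSpec(
            variant_id=row.variant_id, gene=row.gene, position=int(row.position),
            protein_change=row.protein_change,
            carrier_types=("MSC", "PC", "tumor") if row.gene == "CCND1" else ("tumor",),
            carrier_fraction=0.6 if row.gene == "CCND1" else 0.2,
            vaf=0.5, mean_depth=12.0,
        )
        for row in hot.itertuples(index=False)
    ]
    return SimConfig(
        features=features,
        programs=programs,
        n_cells_per_type={t: cells_per_type for t in ATLAS_TYPES},
        marker_assignments=marker_table,
        lineage=[("GMC", 0.0), ("MSC", 0.5), ("tumor", 1.0)],
        n_lineage_cells=n_lineage_cells,
        qc_violations={k: 5 for k in QC_VIOLATION_KINDS},
        cnv_blocks=[block],
        mutations=muts,
        dispersion=2.0,
        libsize_sigma=0.25,
        seed=seed,
    )


def default_signature_matrix() -> pd.DataFrame:
    """Bundled synthetic molecular-subtype reference profiles (genes x
    subtypes), in the four-class scheme MSS/TP53+, MSS/TP53-, MSI, EMT."""
    return pd.read_csv(
        gio.packaged_data("acrg_signatures_synthetic.tsv"), sep="\t", index_col=0
    )


def default_bulk_config(seed: int = 0, n_per_group: int = 120) -> BulkConfig:
    """Bulk meta-cohort default: three prognostic groups mixing the bundled
    subtype profiles (the myofibroblast-high group carries the worst
    hazard), two shifted batches, mild censoring."""
    sig = default_signature_matrix()
    groups = {
        "intestinal": GroupSpec(n_per_group, hazard=0.015,
                                mixture={"MSS_TP53_pos": 0.6, "MSS_TP53_neg": 0.4}),
        "EMT": GroupSpec(n_per_group, hazard=0.020, mixture={"EMT": 0.8, "MSI": 0.2}),
        "EmyoT": GroupSpec(n_per_group, hazard=0.030, mixture={"EmyoT": 1.0}),
    }
    return BulkConfig(
        signature=sig,
        groups=groups,
        batches=[BatchSpec("b0", 0.0, 1.0), BatchSpec("b1", 2.0, 1.3)],
        censor_rate=0.2,
        stages=["normal", "CAG", "IM", "cancer"],
        stage_genes=gio.read_gmt(gio.packaged_data("gene_sets.gmt"))["iCAF"],
        seed=seed,
    )
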