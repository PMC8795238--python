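"""Reading and writing the standard on-disk formats used by the pipeline.

Count matrices travel in the 10x triplet dialect (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``); everything tabular is plain TSV; gene
sets are GMT lines.  In memory, counts live in an :class:`anndata.AnnData`
with cells as ``obs`` and features as ``var``.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FEATURE_COLUMNS = ["gene_id", "symbol", "chromosome", "start"]

MITO_PREFIX = "MT-"
HEMOGLOBIN_SYMBOLS = frozenset(
    {"HBA1", "HBA2", "HBB", "HBD", "HBE1", "HBG1", "HBG2", "HBM", "HBQ1", "HBZ"}
)


def flag_special_genes(features: pd.DataFrame) -> pd.DataFrame:
    """Add boolean ``mito`` / ``hemoglobin`` columns based on gene symbols."""
    out = features.copy()
    sym = out["symbol"].astype(str)
    out["mito"] = sym.str.upper().str.startswith(MITO_PREFIX)
    out["hemoglobin"] = sym.str.upper().isin(HEMOGLOBIN_SYMBOLS)
    return out


def make_anndata(counts, barcodes, features: pd.DataFrame) -> ad.AnnData:
    """Assemble a counts AnnData (cells x genes) with annotated features.

    ``features`` must carry gene_id, symbol, chromosome and 1-based start.
    Raises on duplicated barcodes or a feature table that does not match the
    matrix width.
    """
    counts = sp.csr_matrix(counts)
    barcodes = pd.Index(barcodes, name="barcode").astype(str)
    if barcodes.has_duplicates:
        raise ValueError("duplicate cell barcodes")
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative counts")
    var = flag_special_genes(features.reset_index(drop=True))
    var.index = pd.Index(var["gene_id"].astype(str), name="gene_id")
    adata = ad.AnnData(X=counts, var=var)
    adata.obs_names = barcodes
    return adata


def write_10x_dir(adata: ad.AnnData, outdir: str | os.PathLike) -> Path:
    """Write matrix.mtx / barcodes.tsv / features.tsv (uncompressed 10x dialect).

    The matrix is stored genes x cells, as 10x does.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(adata.X.T), field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.var[FEATURE_COLUMNS].to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    return outdir


def read_10x_dir(indir: str | os.PathLike) -> ad.AnnData:
    """Read a 10x-dialect directory written by :func:`write_10x_dir`."""
    indir = Path(indir)
    mat = scipy.io.mmread(indir / "matrix.mtx").T.tocsr()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None, names=FEATURE_COLUMNS)
    return make_anndata(mat, barcodes, features)


def read_marker_table(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a two-column (cell_type, gene) TSV into an ordered marker map."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["cell_type", "gene"])
    table: dict[str, list[str]] = {}
    for ct, gene in df.itertuples(index=False):
        table.setdefault(str(ct), []).append(str(gene))
    return table


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def packaged_data(name: str) -> Path:
    """Path to a bundled default data file (synthetic defaults)."""
    return Path(__file__).parent / "data" / name


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
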