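"""Gene-set scoring, subtype deconvolution, and tumor-group classification.

A gene-set score is the mean z-scored expression of the set's genes — zero
for a cell sitting at the global mean of every set gene.  Molecular-subtype
composition is estimated by variance-weighted non-negative least squares
against a signature matrix of reference profiles (MSS/TP53+, MSS/TP53-, MSI,
EMT in the four-class scheme).  Tumor cells are grouped into intestinal /
EMT / EmyoT classes from their standardized signature scores, where the
EmyoT call additionally requires the myofibroblast score to exceed the EMT
score (EmyoT cells are myofibroblast-high but EMT-low).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

TUMOR_GROUPS = ("intestinal", "EMT", "EmyoT")
_TIE_PRIORITY = {"EmyoT": 0, "EMT": 1, "intestinal": 2}


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate symbols in gene set {self.name!r}")


def _expr_frame(data) -> pd.DataFrame:
    """Accept an AnnData (symbols from var) or a samples x genes DataFrame."""
    if isinstance(data, ad.AnnData):
        X = np.asarray(sp.csr_matrix(data.X).todense())
        return pd.DataFrame(X, index=data.obs_names, columns=data.var["symbol"].to_numpy())
    return data


def score_gene_set(data, gene_set: GeneSet) -> pd.Series:
    """Mean z-scored expression of the set's genes per cell/sample.

    Genes absent from the matrix are skipped (and reported via the Series'
    ``attrs['missing']``); if none is present an error names the set.
    """
    expr = _expr_frame(data)
    present = [g for g in gene_set.genes if g in expr.columns]
    missing = [g for g in gene_set.genes if g not in expr.columns]
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    sub = expr[present].to_numpy(float)
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    sd[sd == 0] = 1.0
    score = pd.Series(((sub - mu) / sd).mean(axis=1), index=expr.index,
                      name=f"score_{gene_set.name}")
    score.attrs["missing"] = missing
    return score


def deconvolve_subtypes(
    data,
    signature: pd.DataFrame,
    variance_floor: float = 1e-6,
) -> pd.DataFrame:
    """Variance-weighted NNLS of each cell/sample onto signature columns.

    Genes are weighted by the inverse of their variance across the reference
    columns (floor-clamped), then each profile is fit by non-negative least
    squares over the shared genes.  Weights are normalized to sum 1;
    ``label`` is the argmax column, "ambiguous" on exact ties, and an
    all-zero input profile yields label NA with ``flagged`` True.
    """
    expr = _expr_frame(data)
    shared = [g for g in signature.index if g in expr.columns]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between expression and signature")
    S = signature.loc[shared].to_numpy(float)
    w = 1.0 / np.maximum(S.var(axis=1), variance_floor)
    sw = np.sqrt(w)[:, None]
    A = S * sw
    Y = expr[shared].to_numpy(float)
    out = np.zeros((Y.shape[0], S.shape[1]))
    flagged = np.zeros(Y.shape[0], dtype=bool)
    labels: list = []
    cols = list(signature.columns)
    for i, y in enumerate(Y):
        if not np.any(y != 0):
            flagged[i] = True
            labels.append(pd.NA)
            continue
        coef, _ = nnls(A, y * sw.ravel())
        total = coef.sum()
        out[i] = coef / total if total > 0 else coef
        top = out[i].max()
        winners = [c for c, v in zip(cols, out[i]) if v >= top - 1e-9]
        labels.append(winners[0] if len(winners) == 1 else "ambiguous")
    res = pd.DataFrame(out, index=expr.index, columns=cols)
    res["label"] = labels
    res["flagged"] = flagged
    return res


def classify_tumor_groups(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each tumor cell to intestinal / EMT / EmyoT.

    ``scores`` must have the three columns named in :data:`TUMOR_GROUPS`.
    Columns are standardized across cells; the label is the argmax, except
    that an EmyoT call requires the EmyoT score to exceed the EMT score.
    Exact ties break by priority EmyoT > EMT > intestinal and are flagged.
    """
    missing = [c for c in TUMOR_GROUPS if c not in scores.columns]
    if missing:
        raise ValueError(f"missing score columns: {missing}")
    Z = scores[list(TUMOR_GROUPS)].astype(float).copy()
    for c in TUMOR_GROUPS:
        sd = Z[c].std(ddof=0)
        Z[c] = (Z[c] - Z[c].mean()) / (sd if sd > 0 else 1.0)
    labels, tie_flags = [], []
    for _, row in Z.iterrows():
        top = row.max()
        winners = sorted(row.index[row == top], key=_TIE_PRIORITY.get)
        label = winners[0]
        if label == "EmyoT" and not (row["EmyoT"] > row["EMT"] or "EMT" in winners):
            label = "EMT" if row["EMT"] >= row["intestinal"] else "intestinal"
        labels.append(label)
        tie_flags.append(len(winners) > 1)
    return pd.DataFrame(
        {"label": labels, "tied": tie_flags, **{f"z_{c}": Z[c] for c in TUMOR_GROUPS}},
        index=scores.index,
    )


def hypergeometric_enrichment(
    deg_set: set[str], pathways: dict[str, list[str]], universe: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a DEG set in each pathway.

    p = P(X >= k) with N = |universe|, K = |pathway ∩ universe|,
    n = |deg_set|, k = |deg ∩ pathway|.  Pathways disjoint from the universe
    are skipped with a notice row; a BH-adjusted column is included.
    """
    deg = set(deg_set)
    uni = set(universe)
    if not deg <= uni:
        raise ValueError("DEG set must be a subset of the universe")
    rows = []
    for name, genes in pathways.items():
        pw = set(genes) & uni
        if not pw:
            rows.append({"pathway": name, "k": 0, "K": 0, "p": np.nan,
                         "note": "disjoint from universe"})
            continue
        k = len(deg & pw)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(pw), len(deg)))
        rows.append({"pathway": name, "k": k, "K": len(pw), "p": p, "note": ""})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def compare_scores_anova(
    scores: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> tuple[float, float]:
    """One-way ANOVA of a score across groups; returns (F, p).

    Requires at least two groups, each with at least two members; a
    singleton group raises an error naming it.  Exactly identical group
    means give (F=0, p=1).
    """
    s = np.asarray(scores, float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    parts = []
    for lv in levels:
        part = s[g == lv]
        if len(part) < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 members")
        parts.append(part)
    means = [p.mean() for p in parts]
    if np.ptp(means) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*parts)
    return float(f), float(p)
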