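"""Bulk meta-cohort harmonization and survival stratification.

Cohorts profiled on different platforms are merged by intersecting genes,
quantile-normalizing within batch, and standardizing each gene per batch to
the pooled mean/variance (a shrinkage-free batch adjustment).  Groups are
compared by Cox proportional hazards (Efron ties, via lifelines), the
Kaplan–Meier estimator with Greenwood confidence bands, and the log-rank
test.  Score–score association reports Pearson correlation plus a
median-split contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class BulkCohort:
    """Samples x genes expression plus per-sample metadata (batch, group,
    survival time in months, event indicator, optional disease stage)."""

    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.expr.index.equals(self.meta.index):
            raise ValueError("expression and metadata sample indices differ")
        if "time" in self.meta and (self.meta["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        if "event" in self.meta and not self.meta["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization across samples (rows)."""
    vals = expr.to_numpy(float)
    order = np.argsort(vals, axis=1)
    ranks = np.empty_like(order)
    n = vals.shape[1]
    for i in range(vals.shape[0]):
        ranks[i, order[i]] = np.arange(n)
    ref = np.sort(vals, axis=1).mean(axis=0)
    return pd.DataFrame(ref[ranks], index=expr.index, columns=expr.columns)


def harmonize_batches(cohorts: list[BulkCohort]) -> BulkCohort:
    """Merge cohorts into one batch-adjusted meta-cohort.

    Genes are intersected; expression is quantile-normalized within batch,
    then each gene is standardized per batch and rescaled to the pooled
    mean/sd so that batch location/scale differences vanish.
    """
    genes = None
    for c in cohorts:
        genes = set(c.expr.columns) if genes is None else genes & set(c.expr.columns)
    genes = sorted(genes or [])
    if not genes:
        raise ValueError("empty gene intersection across cohorts")
    expr = pd.concat([c.expr[genes] for c in cohorts])
    meta = pd.concat([c.meta for c in cohorts])
    batches = meta["batch"]
    qn = pd.concat(
        [quantile_normalize(expr.loc[batches == b]) for b in pd.unique(batches)]
    ).loc[expr.index]
    pooled_mu, pooled_sd = qn.mean(axis=0), qn.std(axis=0, ddof=0)
    out = qn.copy()
    for b in pd.unique(batches):
        rows = batches == b
        mu = qn.loc[rows].mean(axis=0)
        sd = qn.loc[rows].std(axis=0, ddof=0).replace(0, 1.0)
        out.loc[rows] = (qn.loc[rows] - mu) / sd * pooled_sd + pooled_mu
    return BulkCohort(expr=out, meta=meta)


@dataclass
class SurvivalResult:
    hazard_ratios: pd.DataFrame  # per non-reference group: HR, CI, Wald p
    logrank_p: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    reference: str = ""
    notes: list[str] = field(default_factory=list)


def fit_cox_km(
    meta: pd.DataFrame,
    group_col: str = "group",
    reference: str | None = None,
    horizon: float | None = None,
) -> SurvivalResult:
    """Cox PH (Efron ties) + Kaplan–Meier + log-rank across groups.

    ``meta`` needs time/event columns.  ``reference`` picks the baseline
    group for hazard ratios (default: first by name).  ``horizon`` applies
    administrative censoring at that time (e.g. 60 months for 5-year rates).
    Groups with zero events are flagged as unstable in ``notes``.
    """
    df = meta[[group_col, "time", "event"]].dropna().copy()
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    if horizon is not None:
        over = df["time"] > horizon
        df.loc[over, "time"] = horizon
        df.loc[over, "event"] = 0
    reference = reference or groups[0]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")

    notes = []
    for g in groups:
        if df.loc[df[group_col] == g, "event"].sum() == 0:
            notes.append(f"group {g!r} has zero events; HR unstable")

    dummies = pd.get_dummies(df[group_col], prefix="g", dtype=float)
    ref_col = f"g_{reference}"
    design = pd.concat(
        [df[["time", "event"]], dummies.drop(columns=[ref_col])], axis=1
    )
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")  # Efron ties default
    summ = cph.summary
    hr = pd.DataFrame(
        {
            "group": [c[2:] for c in summ.index],
            "hr": np.exp(summ["coef"].to_numpy()),
            "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
            "wald_p": summ["p"].to_numpy(),
        }
    ).set_index("group")

    curves = {}
    for g in groups:
        sub = df[df[group_col] == g]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        ci = km.confidence_interval_survival_function_
        curves[g] = pd.DataFrame(
            {
                "time": km.survival_function_.index,
                "survival": km.survival_function_["KM_estimate"].to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        ).reset_index(drop=True)

    lr = multivariate_logrank_test(df["time"], df[group_col], df["event"])
    return SurvivalResult(
        hazard_ratios=hr, logrank_p=float(lr.p_value), km_curves=curves,
        reference=reference, notes=notes,
    )


def exponential_hr_mle(meta: pd.DataFrame, group_a: str, group_b: str,
                       group_col: str = "group") -> float:
    """Closed-form exponential MLE hazard ratio (d_a/T_a) / (d_b/T_b)."""
    out = []
    for g in (group_a, group_b):
        sub = meta[meta[group_col] == g]
        d, t = sub["event"].sum(), sub["time"].sum()
        if d == 0 or t == 0:
            raise ValueError(f"group {g!r} has no events or no follow-up")
        out.append(d / t)
    return out[0] / out[1]


@dataclass
class AssociationResult:
    pearson_r: float
    pearson_p: float
    high_low_t: float
    high_low_p: float
    high_mean: float
    low_mean: float


def associate_scores(a: pd.Series, b: pd.Series) -> AssociationResult:
    """Pearson correlation of two per-sample scores plus a median-split test.

    Samples are split at the median of ``a`` into high/low groups and ``b``
    is compared between them by a two-sample t test.  A zero-variance input
    raises (R undefined).
    """
    a, b = a.align(b, join="inner")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero-variance score vector; correlation undefined")
    r, p = stats.pearsonr(a, b)
    high = a > a.median()
    t, tp = stats.ttest_ind(b[high], b[~high])
    return AssociationResult(
        pearson_r=float(r), pearson_p=float(p), high_low_t=float(t),
        high_low_p=float(tp), high_mean=float(b[high].mean()),
        low_mean=float(b[~high].mean()),
    )
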