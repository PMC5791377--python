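"""Covariate-adjusted differential expression, non-amplified overexpressors
with regional epigenetic control, and prevalence/case-count arithmetic.

The differential-expression screen fits a plain per-gene ordinary-least-
squares model of log expression on the contrast plus covariates (subtype,
chromosomal instability, hormone-receptor expression, proliferation), with
two-sided t-tests on the contrast coefficient and Benjamini-Hochberg FDR.
Fold change is reported as the difference of group mean log2 expression, so
"fold change > 2" means |log2 FC| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon_coamp import bh_fdr
from .cohort_io import (
    CopyNumberTable,
    ExpressionTable,
    GeneAnnotation,
    ValidationError,
    warn,
)
from .her2a_calling import HER2CallSet, _round_half_away


# ---------------------------------------------------------------------------
# fold change and the linear-model screen
# ---------------------------------------------------------------------------


def log2_fold_change(expr: ExpressionTable, group_a_mask, group_b_mask) -> pd.Series:
    """Difference of group mean log2 expression (A minus B)."""
    a = pd.Series(group_a_mask).reindex(expr.values.columns).fillna(False).astype(bool)
    b = pd.Series(group_b_mask).reindex(expr.values.columns).fillna(False).astype(bool)
    if not a.any() or not b.any():
        raise ValidationError("both groups must be non-empty")
    return expr.values.loc[:, a].mean(axis=1) - expr.values.loc[:, b].mean(axis=1)


@dataclass
class DgeResult:
    """Per-gene differential-expression statistics."""

    table: pd.DataFrame  # log2fc, p, fdr, hit
    covariates: list

    @property
    def hits(self) -> list:
        return self.table.index[self.table["hit"]].tolist()


def _design_matrix(contrast: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": 1.0, "contrast": contrast.astype(float)})
    if covariates is not None:
        for col in covariates.columns:
            series = covariates[col]
            if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
                X = pd.concat([X, dummies], axis=1)
            else:
                X[col] = series.astype(float)
    return X


def covariate_adjusted_dge(
    expr: ExpressionTable,
    contrast_mask,
    covariates: pd.DataFrame | None = None,
    exclude_genes: list | None = None,
    fdr_cut: float = 0.05,
    fc_cut: float = 2.0,
) -> DgeResult:
    """Per-gene OLS of log expression on contrast + covariates.

    p-values come from the two-sided t-statistic of the contrast coefficient;
    FDR is Benjamini-Hochberg across the tested genes. ``exclude_genes``
    supports dropping e.g. the anchor chromosome. A rank-deficient design
    raises with the collinear column names.
    """
    contrast = (
        pd.Series(contrast_mask).reindex(expr.values.columns).fillna(False).astype(bool)
    )
    if contrast.sum() < 2 or (~contrast).sum() < 2:
        raise ValidationError("need >= 2 samples on each side of the contrast")
    if covariates is not None:
        covariates = covariates.reindex(expr.values.columns)
    X = _design_matrix(contrast, covariates)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValidationError(f"fewer samples ({n}) than model parameters ({p})")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        bad = []
        cols = list(X.columns)
        kept: list = []
        for j in range(p):
            if np.linalg.matrix_rank(Xv[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(cols[j])
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")

    Y = expr.values
    if exclude_genes:
        Y = Y.drop(index=[g for g in exclude_genes if g in Y.index])
    Yv = Y.to_numpy(dtype=float).T  # samples x genes

    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    beta = XtX_inv @ Xv.T @ Yv  # p x genes
    resid = Yv - Xv @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dof)

    lfc = log2_fold_change(ExpressionTable(Y, expr.transform_tag), contrast, ~contrast)
    table = pd.DataFrame(
        {"log2fc": lfc, "coef": beta[1], "p": pvals, "fdr": bh_fdr(pd.Series(pvals, index=Y.index))},
        index=Y.index,
    )
    table["hit"] = (table["fdr"] < fdr_cut) & (table["log2fc"].abs() > np.log2(fc_cut))
    return DgeResult(table=table, covariates=list(X.columns)[2:])


def select_dge_hits(
    results: DgeResult | list,
    fdr_cut: float = 0.05,
    fc_cut: float = 2.0,
) -> list:
    """Genes with FDR < cut and |log2FC| > log2(fc_cut).

    Given several cohort results, a gene is a hit when it meets the criteria
    in at least one cohort.
    """
    if isinstance(results, DgeResult):
        results = [results]
    log2_cut = np.log2(fc_cut)
    hits: set = set()
    for res in results:
        t = res.table
        hits |= set(t.index[(t["fdr"] < fdr_cut) & (t["log2fc"].abs() > log2_cut)])
    return sorted(hits)


# ---------------------------------------------------------------------------
# non-amplified overexpressors and regional control
# ---------------------------------------------------------------------------


def find_nonamplified_overexpressors(calls: HER2CallSet, scheme: str = "ploidy") -> list:
    """Samples overexpressing the anchor without amplification under ``scheme``."""
    df = calls.df
    oe = df["overexpressed"].fillna(False).astype(bool)
    amp = df[f"call_{scheme}"].fillna(False).astype(bool)
    return df.index[oe & ~amp].tolist()


def relative_expression_to_diploid(
    expr: ExpressionTable,
    cn: CopyNumberTable,
    genes: GeneAnnotation,
    window_genes: list,
    anchor: str = "ERBB2",
    strata: pd.Series | None = None,
    max_reference_cn: float = 2.0,
    min_reference: int = 5,
) -> pd.DataFrame:
    """Expression relative to the per-gene median of anchor-diploid samples.

    Per stratum (e.g. cancer type), the median log expression of each window
    gene over the reference samples (anchor total CN <= ``max_reference_cn``)
    is subtracted. Strata with fewer than ``min_reference`` reference samples
    are skipped with a warning and return NaN columns.
    """
    anchor_id = genes.resolve(anchor)
    window = [genes.resolve(g) for g in window_genes]
    missing = [g for g in window if g not in expr.values.index]
    if missing:
        raise ValidationError(f"window genes missing from expression: {missing}")
    anchor_cn = cn.values.loc[anchor_id].reindex(expr.values.columns)
    if strata is None:
        strata = pd.Series("all", index=expr.values.columns)
    else:
        strata = pd.Series(strata).reindex(expr.values.columns)

    out = pd.DataFrame(np.nan, index=window, columns=expr.values.columns)
    for name, members in strata.groupby(strata):
        cols = members.index
        ref = cols[(anchor_cn[cols] <= max_reference_cn).fillna(False)]
        if len(ref) < min_reference:
            warn(f"stratum {name!r}: only {len(ref)} reference samples; skipped")
            continue
        med = expr.values.loc[window, ref].median(axis=1)
        out.loc[window, cols] = expr.values.loc[window, cols].sub(med, axis=0).to_numpy()
    return out


def regional_control_flag(
    relative_expr: pd.DataFrame,
    samples: list,
    neighbor_genes: tuple = ("PGAP3", "MIEN1", "GRB7"),
    distal_genes: tuple = ("MED1", "CDK12", "NR1D1", "TOP2A"),
    delta: float = 1.0,
) -> pd.Series:
    """True when all neighbor genes exceed +delta relative expression and no
    distal gene does — the signature of regional (non-amplification)
    upregulation rather than an arm-level pattern. Samples should already be
    non-amplified overexpressors; missing neighbor genes yield NA."""
    out = {}
    neighbors = [g for g in neighbor_genes if g in relative_expr.index]
    distals = [g for g in distal_genes if g in relative_expr.index]
    complete = len(neighbors) == len(neighbor_genes)
    if not complete:
        warn(
            f"neighbor genes absent from the relative-expression window: "
            f"{sorted(set(neighbor_genes) - set(neighbors))}; flags are NA"
        )
    for s in samples:
        if not complete or relative_expr[s].loc[neighbors].isna().any():
            out[s] = pd.NA
            continue
        up = (relative_expr[s].loc[neighbors] > delta).all()
        distal_up = (relative_expr[s].loc[distals] > delta).any() if distals else False
        out[s] = bool(up and not distal_up)
    return pd.Series(out, dtype="boolean")


def methylation_group_test(
    mvalues: pd.DataFrame,
    probe_map: pd.DataFrame,
    her2a: pd.Series,
    overexpressed: pd.Series,
    genes: tuple = ("ERBB2", "PGAP3", "MIEN1", "GRB7"),
    fdr_cut: float = 0.05,
    tss_window: int = 2000,
) -> pd.DataFrame:
    """Kruskal-Wallis test per CpG probe across the four HER2A x overexpression groups.

    Probes are restricted to the gene bodies of ``genes`` or at most
    ``tss_window`` bp upstream of their TSS. Reports per-probe group mean
    M-values, the tie-corrected Kruskal-Wallis p and BH FDR. Empty groups are
    dropped (with a notice); fewer than two non-empty groups is an error.
    """
    keep = probe_map.index[
        probe_map["gene"].isin(genes)
        & (probe_map["in_gene_body"] | (probe_map["dist_to_tss"] >= -tss_window))
    ]
    keep = [p for p in keep if p in mvalues.index]
    if not keep:
        raise ValidationError("no probes map to the requested genes within the window")

    samples = mvalues.columns
    h = pd.Series(her2a).reindex(samples).fillna(False).astype(bool)
    oe = pd.Series(overexpressed).reindex(samples).fillna(False).astype(bool)
    group = pd.Series("", index=samples, dtype=object)
    group[h & oe] = "HER2A_oe"
    group[h & ~oe] = "HER2A_non_oe"
    group[~h & oe] = "nonHER2A_oe"
    group[~h & ~oe] = "nonHER2A_non_oe"
    names = [g for g in group.unique() if (group == g).any()]
    if len(names) < 4:
        warn(f"only {len(names)} non-empty methylation groups; testing across those")
    if len(names) < 2:
        raise ValidationError("need >= 2 non-empty groups for the Kruskal-Wallis test")

    rows = []
    for probe in keep:
        vals = [mvalues.loc[probe, group == g].to_numpy(dtype=float) for g in names]
        flat = np.concatenate(vals)
        if np.ptp(flat) == 0:  # identical values carry no group signal
            p = 1.0
        else:
            p = float(stats.kruskal(*vals)[1])
        row = {"probe": probe, "gene": probe_map.loc[probe, "gene"], "p": p}
        for g, v in zip(names, vals):
            row[f"mean_M_{g}"] = float(np.mean(v)) if len(v) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("probe")
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < fdr_cut
    return out


# ---------------------------------------------------------------------------
# prevalence / case-count arithmetic
# ---------------------------------------------------------------------------


def prevalence_percent(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded half away from zero to ``decimals``."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(_round_half_away(100.0 * k / n, decimals))


def estimate_her2a_cases(prevalence_pct: float, annual_cases: int) -> int:
    """Annual amplified-case estimate: round(prevalence/100 * cases), half away from zero."""
    if prevalence_pct < 0 or prevalence_pct > 100:
        raise ValidationError("prevalence_pct must be in [0, 100]")
    if annual_cases < 0:
        raise ValidationError("annual_cases must be non-negative")
    return int(_round_half_away(prevalence_pct / 100.0 * annual_cases))


def table3_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Prevalence and estimated-case table from (cancer, k, n, annual_cases).

    Each row's estimate uses the rounded prevalence percentage unless its
    ``use_unrounded`` flag is set, in which case the raw fraction k/n is used
    (some published tables mix the two conventions). Rows without annual case
    figures get NA estimates; a totals row sums the available estimates.
    """
    req = {"cancer", "k", "n"}
    if not req <= set(rows.columns):
        raise ValidationError(f"table3_summary requires columns {sorted(req)}")
    out = rows.copy()
    out["prevalence_pct"] = [
        prevalence_percent(int(k), int(n)) for k, n in zip(out["k"], out["n"])
    ]
    estimates = []
    for _, r in out.iterrows():
        if "annual_cases" not in out.columns or pd.isna(r.get("annual_cases")):
            estimates.append(pd.NA)
            continue
        if bool(r.get("use_unrounded", False)):
            pct = 100.0 * r["k"] / r["n"]
        else:
            pct = r["prevalence_pct"]
        estimates.append(estimate_her2a_cases(pct, int(r["annual_cases"])))
    out["estimated_her2a_cases"] = estimates
    return out
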