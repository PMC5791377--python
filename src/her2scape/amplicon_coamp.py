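"""Amplicon boundary mapping and the genome-wide co-amplification screen.

The amplicon profile reports, per gene on the anchor chromosome, the fraction
of amplified (HER2A) samples in which the gene itself is amplified; core and
broad amplicon spans are the maximal contiguous runs above a high (e.g. 0.8
to 0.92) or moderate (0.6) fraction threshold that contain the anchor. The
boundary analysis defaults to the total-copies rule (total CN >= 5) while the
genome-wide Fisher co-amplification screen defaults to the ploidy-corrected
rule (relcn >= 4); both are flags because the two analyses use different
definitions of "amplified".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CopyNumberTable, GeneAnnotation, ValidationError, warn

AMP_RULES = ("total_ge_5", "relcn_ge_4")


def _amplified_matrix(cn: CopyNumberTable, amp_rule: str) -> pd.DataFrame:
    if amp_rule == "total_ge_5":
        return cn.values >= 5.0
    if amp_rule == "relcn_ge_4":
        if cn.ploidy is None or cn.ploidy.isna().all():
            raise ValidationError("relcn_ge_4 rule requires per-sample ploidy")
        rel = 2.0 * cn.values.div(cn.ploidy, axis=1)
        return rel >= 4.0
    raise ValueError(f"unknown amp_rule {amp_rule!r}; expected one of {AMP_RULES}")


def amplified_fraction_per_gene(
    cn: CopyNumberTable,
    her2a_mask: pd.Series,
    amp_rule: str = "total_ge_5",
    exclude_genes: list | None = None,
) -> pd.Series:
    """Per-gene fraction of masked samples in which the gene is amplified.

    Samples with missing CN for a gene are excluded from that gene's
    denominator. ``exclude_genes`` (e.g. germline-artifact runs) are dropped.
    """
    mask = pd.Series(her2a_mask).reindex(cn.values.columns).fillna(False).astype(bool)
    if not mask.any():
        raise ValidationError("her2a_mask selects no samples")
    amp = _amplified_matrix(cn, amp_rule)
    sub = amp.loc[:, mask]
    present = cn.values.loc[:, mask].notna()
    frac = (sub & present).sum(axis=1) / present.sum(axis=1)
    if exclude_genes:
        frac = frac.drop(index=[g for g in exclude_genes if g in frac.index])
    return frac


@dataclass
class AmpliconProfile:
    """Ordered per-gene amplified fractions on the anchor chromosome plus spans."""

    fractions: pd.Series  # annotation order on the anchor chromosome
    mean_cn_amplified: pd.Series  # mean CN among samples where the gene is amplified
    core_genes: list
    core_bp: int
    broad_genes: list
    broad_bp: int
    core_threshold: float
    broad_threshold: float
    amp_rule: str


def amplicon_boundaries(
    fractions: pd.Series,
    genes: GeneAnnotation,
    anchor: str,
    fraction_threshold: float,
) -> tuple:
    """Maximal contiguous gene run with fraction >= threshold containing the anchor.

    Returns (gene_id list, bp extent); the bp extent is end(last) - start(first)
    + 1 (1-based inclusive). If the anchor itself falls below the threshold the
    span is empty, with a warning.
    """
    anchor_id = genes.resolve(anchor)
    if anchor_id not in fractions.index:
        raise ValidationError(f"anchor {anchor!r} absent from the fraction profile")
    chrom = genes.df.loc[anchor_id, "chrom"]
    order = [g for g in genes.on_chromosome(chrom).index if g in fractions.index]
    vals = fractions.loc[order].to_numpy()
    pos = order.index(anchor_id)
    if vals[pos] < fraction_threshold:
        warn(f"anchor {anchor!r} below the fraction threshold; amplicon span is empty")
        return [], 0
    lo = pos
    while lo > 0 and vals[lo - 1] >= fraction_threshold:
        lo -= 1
    hi = pos
    while hi < len(order) - 1 and vals[hi + 1] >= fraction_threshold:
        hi += 1
    span = order[lo : hi + 1]
    bp = int(genes.df.loc[span[-1], "end"] - genes.df.loc[span[0], "start"] + 1)
    return span, bp


def amplicon_profile(
    cn: CopyNumberTable,
    genes: GeneAnnotation,
    her2a_mask: pd.Series,
    anchor: str = "ERBB2",
    amp_rule: str = "total_ge_5",
    core_threshold: float = 0.8,
    broad_threshold: float = 0.6,
    exclude_genes: list | None = None,
) -> AmpliconProfile:
    """Profile the amplicon around the anchor: fractions, mean CN, core/broad spans."""
    anchor_id = genes.resolve(anchor)
    chrom = genes.df.loc[anchor_id, "chrom"]
    chrom_genes = [g for g in genes.on_chromosome(chrom).index if g in cn.values.index]
    frac_all = amplified_fraction_per_gene(cn, her2a_mask, amp_rule, exclude_genes)
    frac = frac_all.loc[[g for g in chrom_genes if g in frac_all.index]]

    amp = _amplified_matrix(cn, amp_rule)
    mask = pd.Series(her2a_mask).reindex(cn.values.columns).fillna(False).astype(bool)
    masked_cn = cn.values.loc[frac.index, mask]
    masked_amp = amp.loc[frac.index, mask]
    mean_cn = masked_cn.where(masked_amp).mean(axis=1)

    core, core_bp = amplicon_boundaries(frac, genes, anchor, core_threshold)
    broad, broad_bp = amplicon_boundaries(frac, genes, anchor, broad_threshold)
    return AmpliconProfile(
        fractions=frac,
        mean_cn_amplified=mean_cn,
        core_genes=core,
        core_bp=core_bp,
        broad_genes=broad,
        broad_bp=broad_bp,
        core_threshold=core_threshold,
        broad_threshold=broad_threshold,
        amp_rule=amp_rule,
    )


# ---------------------------------------------------------------------------
# co-amplification screen
# ---------------------------------------------------------------------------


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_coamplification(
    cn: CopyNumberTable,
    her2a_mask: pd.Series,
    genes: GeneAnnotation | None = None,
    amp_rule: str = "relcn_ge_4",
    cin_strata: pd.Series | None = None,
) -> pd.Series:
    """Two-sided Fisher exact p per gene for amplification x HER2A association.

    With ``cin_strata`` given (e.g. CIN tertile labels), a Cochran-Mantel-
    Haenszel test stratified on instability replaces the plain Fisher test,
    to separate co-amplification from a shared instability background. Genes
    with all-missing CN get NaN.
    """
    mask = pd.Series(her2a_mask).reindex(cn.values.columns).fillna(False).astype(bool)
    if not mask.any() or mask.all():
        raise ValidationError("her2a_mask must split samples into two non-empty classes")
    amp = _amplified_matrix(cn, amp_rule)
    present = cn.values.notna()

    pvals = {}
    if cin_strata is not None:
        strata = pd.Series(cin_strata).reindex(cn.values.columns)
        from statsmodels.stats.contingency_tables import StratifiedTable

        for g in amp.index:
            ok = present.loc[g]
            if not ok.any():
                pvals[g] = np.nan
                continue
            tables = []
            for _, members in strata[ok].groupby(strata[ok]):
                idx = members.index
                a = int((amp.loc[g, idx] & mask[idx]).sum())
                b = int((amp.loc[g, idx] & ~mask[idx]).sum())
                c = int((~amp.loc[g, idx] & mask[idx]).sum())
                d = int((~amp.loc[g, idx] & ~mask[idx]).sum())
                tables.append(np.array([[a, b], [c, d]]))
            try:
                pvals[g] = float(StratifiedTable(tables).test_null_odds(correction=False).pvalue)
            except (ValueError, ZeroDivisionError):
                pvals[g] = np.nan
        return pd.Series(pvals, name="p")

    m = mask.to_numpy()
    for g in amp.index:
        ok = present.loc[g].to_numpy()
        if not ok.any():
            pvals[g] = np.nan
            continue
        av = amp.loc[g].to_numpy()[ok]
        mv = m[ok]
        a = int((av & mv).sum())
        b = int((av & ~mv).sum())
        c = int((~av & mv).sum())
        d = int((~av & ~mv).sum())
        pvals[g] = fisher_exact_p(a, b, c, d)
    return pd.Series(pvals, name="p")


def bh_fdr(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unchanged."""
    p = pd.Series(pvalues, dtype=float)
    ok = p.notna()
    vals = p[ok].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    adj = p.copy()
    if ok.any():
        adj[ok] = multipletests(vals, method="fdr_bh")[1]
    if isinstance(pvalues, (pd.Series,)):
        return adj
    return adj.to_numpy()


@dataclass
class CoampRegion:
    """A contiguous run of genes significantly co-amplified with the anchor."""

    chromosome: str
    genes: list
    first_gene: str
    last_gene: str
    n_genes: int
    fdr: pd.Series = field(repr=False, default=None)
    median_pct_her2a: float = np.nan
    iqr_pct_her2a: float = np.nan
    median_pct_other: float = np.nan
    iqr_pct_other: float = np.nan


def merge_coamp_regions(
    fdr: pd.Series,
    genes: GeneAnnotation,
    fdr_cutoff: float = 0.05,
    max_gap_genes: int = 0,
) -> list:
    """Group significant genes into contiguous regions per chromosome.

    Runs may bridge up to ``max_gap_genes`` interior non-significant genes;
    regions of a single gene are allowed.
    """
    regions = []
    for chrom, sub in genes.df.groupby("chrom", sort=False):
        order = [g for g in sub.index if g in fdr.index]
        sig = [g for g in order if pd.notna(fdr[g]) and fdr[g] < fdr_cutoff]
        if not sig:
            continue
        pos = {g: i for i, g in enumerate(order)}
        current = [sig[0]]
        for g in sig[1:]:
            if pos[g] - pos[current[-1]] - 1 <= max_gap_genes:
                current.append(g)
            else:
                regions.append(_make_region(chrom, current, order, pos, fdr))
                current = [g]
        regions.append(_make_region(chrom, current, order, pos, fdr))
    return regions


def _make_region(chrom, sig_run, order, pos, fdr) -> CoampRegion:
    members = order[pos[sig_run[0]] : pos[sig_run[-1]] + 1]
    return CoampRegion(
        chromosome=str(chrom),
        genes=members,
        first_gene=members[0],
        last_gene=members[-1],
        n_genes=len(members),
        fdr=fdr.loc[members],
    )


def summarize_region(
    region: CoampRegion,
    pct_her2a: pd.Series,
    pct_other: pd.Series,
) -> CoampRegion:
    """Fill in median amplified percentage and IQR per class for a region.

    The IQR is the 75th minus the 25th percentile with linear interpolation.
    """
    if not region.genes:
        raise ValidationError("region is empty")

    def med_iqr(series):
        v = series.reindex(region.genes).dropna().to_numpy()
        if len(v) == 0:
            return np.nan, np.nan
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        return float(q50), float(q75 - q25)

    region.median_pct_her2a, region.iqr_pct_her2a = med_iqr(pct_her2a)
    region.median_pct_other, region.iqr_pct_other = med_iqr(pct_other)
    return region


def coamp_screen(
    cn: CopyNumberTable,
    genes: GeneAnnotation,
    her2a_mask: pd.Series,
    amp_rule: str = "relcn_ge_4",
    fdr_cutoff: float = 0.05,
    max_gap_genes: int = 0,
    exclude_chromosome: str | None = None,
    cin_strata: pd.Series | None = None,
) -> tuple:
    """End-to-end screen: Fisher p, BH FDR and summarized regions.

    ``exclude_chromosome`` drops the anchor chromosome so the amplicon itself
    does not dominate the region list. Returns (per-gene table, regions).
    """
    p = fisher_coamplification(cn, her2a_mask, genes, amp_rule, cin_strata)
    if exclude_chromosome is not None:
        keep = genes.df.index[genes.df["chrom"] != str(exclude_chromosome)]
        p = p.loc[[g for g in p.index if g in set(keep)]]
    fdr = bh_fdr(p)
    mask = pd.Series(her2a_mask).reindex(cn.values.columns).fillna(False).astype(bool)
    pct_a = 100.0 * amplified_fraction_per_gene(cn, mask, amp_rule)
    pct_o = 100.0 * amplified_fraction_per_gene(cn, ~mask, amp_rule)
    regions = [
        summarize_region(r, pct_a, pct_o)
        for r in merge_coamp_regions(fdr, genes, fdr_cutoff, max_gap_genes)
    ]
    table = pd.DataFrame({"p": p, "fdr": fdr})
    return table, regions


def regions_to_frame(regions: list) -> pd.DataFrame:
    """Region list as a table mirroring the co-amplification summary layout."""
    rows = [
        {
            "chrom": r.chromosome,
            "n_genes": r.n_genes,
            "first_gene": r.first_gene,
            "last_gene": r.last_gene,
            "median_amplified_pct_her2a": r.median_pct_her2a,
            "iqr_her2a": r.iqr_pct_her2a,
            "median_amplified_pct_other": r.median_pct_other,
            "iqr_other": r.iqr_pct_other,
        }
        for r in regions
    ]
    return pd.DataFrame(rows)
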