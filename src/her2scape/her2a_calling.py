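"""HER2 amplification calling, bimodal thresholds, concordance and CIN.

Three classification schemes are supported:

* ``ploidy``     — ploidy-corrected copies 2*cn/ploidy >= 4 (the primary
  definition; equivalently copy-to-ploidy ratio >= 2),
* ``total``      — total copy number >= 5 (the fallback when ploidy is
  unavailable, as for targeted CN panels),
* ``centromere`` — centromere-corrected copies 2*cn / mean(p-arm gene cn) >= 4.

Ploidy-corrected copy number is reported on the x2 scale (a diploid gene in a
diploid genome is 2) so the >= 4 cutoff applies literally. All cutoffs are
inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .cohort_io import (
    CopyNumberTable,
    ExpressionTable,
    GeneAnnotation,
    SampleTable,
    SegmentSet,
    ValidationError,
    warn,
)

HER2A_RELCN_CUTOFF = 4.0
HER2A_TOTAL_CUTOFF = 5.0

# HER2 kinase/extracellular-domain mutations with demonstrated activating
# effect (increased kinase activity, transformation, or drug sensitization)
ACTIVATING_HER2_MUTATIONS = frozenset(
    ["G309A", "S310F", "L755S", "D769H", "D769Y", "V777L", "V842I", "T862A"]
)

_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*])$")


def relative_copy_number(total_cn, ploidy):
    """Ploidy-corrected copy number 2*cn/ploidy (diploid genome maps to 2)."""
    total_cn = np.asarray(total_cn, dtype=float)
    ploidy = np.asarray(ploidy, dtype=float)
    if np.any(ploidy[np.isfinite(ploidy)] <= 0):
        raise ValidationError("ploidy must be > 0")
    with np.errstate(invalid="ignore"):
        out = 2.0 * total_cn / ploidy
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class HER2CallSet:
    """Per-sample amplification calls under the three schemes.

    ``df`` columns: relcn, call_ploidy, call_total, call_centromere (nullable
    booleans, NA when inputs are absent), call (the selected scheme),
    overexpressed (filled by :func:`set_overexpression`), q17_group.
    """

    df: pd.DataFrame
    scheme: str
    anchor: str

    def calls(self, scheme: str | None = None) -> pd.Series:
        scheme = scheme or self.scheme
        return self.df[f"call_{scheme}"]


def call_her2a(
    cn: CopyNumberTable,
    genes: GeneAnnotation,
    scheme: str = "ploidy",
    anchor: str = "ERBB2",
) -> HER2CallSet:
    """Call HER2 amplification per sample under the requested scheme.

    All three scheme columns are computed where inputs allow; the ``call``
    column reflects ``scheme``. With ploidy absent under the ploidy scheme the
    calls are NA and a warning recommends the total-copies fallback.
    """
    if scheme not in ("ploidy", "total", "centromere"):
        raise ValueError(f"unknown scheme {scheme!r}")
    anchor_id = genes.resolve(anchor)
    if anchor_id not in cn.values.index:
        raise ValidationError(f"anchor gene {anchor!r} missing from CN table")
    anchor_cn = cn.values.loc[anchor_id]

    if cn.ploidy is not None and cn.ploidy.notna().any():
        relcn = 2.0 * anchor_cn / cn.ploidy
    else:
        relcn = pd.Series(np.nan, index=cn.values.columns)
    call_ploidy = pd.array(relcn >= HER2A_RELCN_CUTOFF, dtype="boolean")
    call_ploidy[relcn.isna().to_numpy()] = pd.NA
    if scheme == "ploidy" and relcn.isna().all():
        warn(
            "ploidy unavailable for all samples under the ploidy scheme; "
            "calls are NA - consider scheme='total' (total HER2 copies >= 5)"
        )

    call_total = pd.array(anchor_cn >= HER2A_TOTAL_CUTOFF, dtype="boolean")
    call_total[anchor_cn.isna().to_numpy()] = pd.NA

    chrom = genes.df.loc[anchor_id, "chrom"]
    p_genes = [g for g in genes.arm_genes(chrom, "p") if g in cn.values.index]
    if p_genes:
        p_mean = cn.values.loc[p_genes].mean(axis=0)
        centro_copies = 2.0 * anchor_cn / p_mean
        call_centro = pd.array(centro_copies >= HER2A_RELCN_CUTOFF, dtype="boolean")
        call_centro[centro_copies.isna().to_numpy()] = pd.NA
    else:
        centro_copies = pd.Series(np.nan, index=cn.values.columns)
        call_centro = pd.array([pd.NA] * len(cn.values.columns), dtype="boolean")
        if scheme == "centromere":
            raise ValidationError(
                f"no p-arm genes on chromosome {chrom} for the centromere scheme"
            )

    df = pd.DataFrame(
        {
            "relcn": relcn,
            "centromere_corrected": centro_copies,
            "call_ploidy": call_ploidy,
            "call_total": call_total,
            "call_centromere": call_centro,
        },
        index=cn.values.columns,
    )
    df["call"] = df[f"call_{scheme}"]
    df["overexpressed"] = pd.array([pd.NA] * len(df), dtype="boolean")
    df["q17_group"] = pd.Series(pd.NA, index=df.index, dtype="object")
    return HER2CallSet(df=df, scheme=scheme, anchor=anchor_id)


# ---------------------------------------------------------------------------
# bimodal threshold
# ---------------------------------------------------------------------------


@dataclass
class MixtureThreshold:
    """Two-component Gaussian mixture fit and the derived bimodal threshold.

    The threshold is the smallest point between the two component means where
    the posterior membership probabilities are equal — the midpoint for equal
    weights and variances, and well defined for unequal variances where a
    density minimum may not sit between the means. ``low_confidence`` flags
    fits whose component means are within one (larger) standard deviation of
    each other, i.e. data without convincing bimodality.
    """

    means: tuple
    sds: tuple
    weights: tuple
    threshold: float
    model_family: str  # equal_variance | unequal_variance
    bic: float
    converged: bool
    low_confidence: bool = False


def _posterior_equality_point(m1, s1, w1, m2, s2, w2):
    """Smallest x in (m1, m2) with w1*N(x;m1,s1) = w2*N(x;m2,s2)."""
    if np.isclose(s1, s2):
        mid = 0.5 * (m1 + m2)
        if w1 != w2:
            mid += s1**2 * np.log(w1 / w2) / (m2 - m1)
        return float(mid) if m1 < mid < m2 else np.nan
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log((w1 * s2) / (w2 * s1))
    roots = np.roots([a, b, c])
    roots = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and m1 < r.real < m2)
    return float(roots[0]) if roots else np.nan


def fit_bimodal_threshold(
    values, seed: int = 0, max_iter: int = 1000, family: str = "auto"
) -> MixtureThreshold:
    """EM fit of two-component univariate Gaussian mixtures and the bimodal cutoff.

    With ``family='auto'`` both the equal-variance and unequal-variance
    families are fitted and the one with lower BIC wins; a family can also be
    forced. EM is initialized deterministically from the 25th and 75th
    percentiles with equal weights, tolerance 1e-8. Degenerate input (all
    values equal) raises; non-convergence is flagged with a NaN threshold.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise ValidationError(f"need >= 20 finite values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate data: all values equal")
    X = x.reshape(-1, 1)
    q25, q75 = np.percentile(x, [25, 75])
    var0 = max(x.var(), 1e-6)

    families = (("equal_variance", "tied"), ("unequal_variance", "full"))
    if family != "auto":
        families = tuple(f for f in families if f[0] == family)
        if not families:
            raise ValueError(f"unknown mixture family {family!r}")
    fits = {}
    for family, cov_type in families:
        prec = var0 if cov_type == "tied" else np.array([[[1 / var0]], [[1 / var0]]])
        gm = GaussianMixture(
            n_components=2,
            covariance_type=cov_type,
            means_init=np.array([[q25], [q75]]),
            weights_init=np.array([0.5, 0.5]),
            precisions_init=np.array([[1 / var0]]) if cov_type == "tied" else prec,
            tol=1e-8,
            max_iter=max_iter,
            n_init=1,
            random_state=seed,
        )
        gm.fit(X)
        fits[family] = gm

    family = min(fits, key=lambda f: fits[f].bic(X))
    gm = fits[family]
    means = gm.means_.ravel()
    if family == "equal_variance":
        sds = np.array([np.sqrt(gm.covariances_[0, 0])] * 2)
    else:
        sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = gm.weights_[order]

    converged = bool(gm.converged_)
    low_conf = (abs(m2 - m1) < max(s1, s2)) or not converged
    threshold = np.nan
    if converged:
        threshold = _posterior_equality_point(m1, s1, w1, m2, s2, w2)
        if not np.isfinite(threshold):
            low_conf = True
    return MixtureThreshold(
        means=(float(m1), float(m2)),
        sds=(float(s1), float(s2)),
        weights=(float(w1), float(w2)),
        threshold=float(threshold),
        model_family=family,
        bic=float(gm.bic(X)),
        converged=converged,
        low_confidence=bool(low_conf),
    )


def call_overexpression(
    expr: ExpressionTable,
    gene: str,
    threshold: float,
    expected_transform: str | None = None,
) -> pd.Series:
    """Boolean per sample: expression of ``gene`` >= ``threshold`` (inclusive)."""
    if gene not in expr.values.index:
        raise ValidationError(f"gene {gene!r} missing from expression table")
    if expected_transform is not None and expected_transform != expr.transform_tag:
        warn(
            f"threshold was derived on scale {expected_transform!r} but the table "
            f"declares {expr.transform_tag!r}"
        )
    return expr.values.loc[gene] >= threshold


def set_overexpression(calls: HER2CallSet, overexpressed: pd.Series) -> HER2CallSet:
    calls.df["overexpressed"] = pd.array(
        overexpressed.reindex(calls.df.index), dtype="boolean"
    )
    return calls


# ---------------------------------------------------------------------------
# concordance / McNemar
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    table: np.ndarray  # [[both+, a only], [b only, both-]]
    concordance: float
    precision: float
    recall: float
    mcnemar_p: float
    n: int
    label_a: str = "a"
    label_b: str = "b"


def mcnemar_test(b: int, c: int) -> float:
    """Two-sided McNemar p from the discordant-pair counts.

    Exact binomial when b + c < 25, chi-square without continuity correction
    otherwise (the large-sample regime where the correction matters little).
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n < 25:
        return min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
    chi2 = (b - c) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def concordance_table(
    calls_a, calls_b, label_a: str = "a", label_b: str = "b"
) -> ConcordanceReport:
    """2x2 agreement of two paired boolean call vectors (``a`` vs reference ``b``)."""
    a = pd.Series(calls_a)
    b = pd.Series(calls_b)
    if isinstance(calls_b, pd.Series) and isinstance(calls_a, pd.Series):
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
    keep = a.notna().to_numpy() & b.notna().to_numpy()
    a = a[keep].astype(bool).to_numpy()
    b = b[keep].astype(bool).to_numpy()
    n = len(a)
    if n == 0:
        raise ValidationError("no overlapping non-NA samples between the call vectors")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    tn = int((~a & ~b).sum())
    return ConcordanceReport(
        table=np.array([[tp, fp], [fn, tn]]),
        concordance=(tp + tn) / n,
        precision=tp / (tp + fp) if tp + fp else np.nan,
        recall=tp / (tp + fn) if tp + fn else np.nan,
        mcnemar_p=mcnemar_test(fp, fn),
        n=n,
        label_a=label_a,
        label_b=label_b,
    )


# ---------------------------------------------------------------------------
# chromosomal instability
# ---------------------------------------------------------------------------


@dataclass
class CINProfile:
    """Per-sample autosomal segment counts and per-chromosome breaks/kb."""

    segment_count: pd.Series
    breaks_per_kb: pd.DataFrame  # samples x chromosomes


def _is_autosome(chrom: str) -> bool:
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    return c.isdigit()


def cin_segment_count(
    segments: SegmentSet,
    genes: GeneAnnotation | None = None,
    merge_tol: float = 1e-6,
) -> CINProfile:
    """CIN as the number of autosomal segments with distinct copy levels.

    Adjacent same-chromosome segments whose CN differs by at most ``merge_tol``
    are merged before counting, so the statistic is invariant to splitting a
    segment into equal-CN pieces. breaks/kb per chromosome is
    (merged segment count - 1) / covered length in kb.
    """
    counts = {}
    breaks: dict = {}
    for sample, sub in segments.df.groupby("sample", sort=True):
        total = 0
        row = {}
        any_autosome = False
        for chrom, seg in sub.groupby("chrom"):
            if not _is_autosome(chrom):
                continue
            any_autosome = True
            seg = seg.sort_values("start")
            cn = seg["total_cn"].to_numpy()
            distinct = 1 + int((np.abs(np.diff(cn)) > merge_tol).sum())
            total += distinct
            length_kb = (seg["end"].max() - seg["start"].min() + 1) / 1000.0
            row[chrom] = (distinct - 1) / length_kb
        if not any_autosome:
            warn(f"sample {sample} has no autosomal segments; CIN is NA")
            counts[sample] = np.nan
        else:
            counts[sample] = total
        breaks[sample] = row
    return CINProfile(
        segment_count=pd.Series(counts, name="segment_count"),
        breaks_per_kb=pd.DataFrame(breaks).T.sort_index(),
    )


# ---------------------------------------------------------------------------
# 17q groups, germline artifacts, mutations, subtype cross-tab
# ---------------------------------------------------------------------------


def classify_17q_group(
    cn: CopyNumberTable,
    genes: GeneAnnotation,
    chrom: str = "17",
    arm: str = "q",
) -> pd.Series:
    """Per-sample q-arm event class from total gene copy number.

    arm_amp: >= 80% of q-arm genes at total CN >= 5; gain: >= 80% between 2.5
    and 5; diploid: > 50% below 2.5. Precedence arm_amp > gain > diploid;
    samples matching no rule get the class of the modal CN bin, flagged with a
    '*' suffix.
    """
    q_genes = [g for g in genes.arm_genes(chrom, arm) if g in cn.values.index]
    if len(q_genes) < 10:
        raise ValidationError(
            f"need >= 10 {arm}-arm genes on chromosome {chrom}, found {len(q_genes)}"
        )
    sub = cn.values.loc[q_genes]
    out = {}
    for sample in sub.columns:
        v = sub[sample].dropna().to_numpy()
        if len(v) < 10:
            out[sample] = pd.NA
            continue
        f_amp = (v >= 5).mean()
        f_gain = ((v >= 2.5) & (v < 5)).mean()
        f_dip = (v < 2.5).mean()
        if f_amp >= 0.8:
            out[sample] = "arm_amp"
        elif f_gain >= 0.8:
            out[sample] = "gain"
        elif f_dip > 0.5:
            out[sample] = "diploid"
        else:
            modal = ["diploid", "gain", "arm_amp"][int(np.argmax([f_dip, f_gain, f_amp]))]
            out[sample] = modal + "*"
    return pd.Series(out, name="q17_group")


def find_germline_artifact_regions(
    cn_normals: CopyNumberTable,
    genes: GeneAnnotation,
    high: float = 2.4,
    low: float = 1.6,
    min_fraction: float = 0.05,
    min_normals: int = 20,
) -> list:
    """Gene runs recurrently aberrant in normal tissue (germline CN artifacts).

    A gene is flagged when the fraction of normals with CN > ``high`` or
    CN < ``low`` is at least ``min_fraction``; flagged genes are returned as
    maximal contiguous runs (lists of gene_ids in annotation order) so
    downstream amplified-fraction plots and screens can mask them.
    """
    n = cn_normals.values.shape[1]
    if n == 0:
        warn("no normal samples; returning no germline artifact regions")
        return []
    if n < min_normals:
        raise ValidationError(f"need >= {min_normals} normal samples, got {n}")
    vals = cn_normals.values
    frac = (((vals > high) | (vals < low)).sum(axis=1) / vals.notna().sum(axis=1)).fillna(0)
    flagged = frac >= min_fraction

    runs = []
    current: list = []
    prev_key = None
    for g in genes.df.index:
        if g not in flagged.index or not flagged[g]:
            if current:
                runs.append(current)
                current = []
            prev_key = None
            continue
        chrom = genes.df.loc[g, "chrom"]
        if prev_key is not None and prev_key != chrom:
            runs.append(current)
            current = []
        current.append(g)
        prev_key = chrom
    if current:
        runs.append(current)
    return runs


def classify_her2_mutation(protein_change: str) -> str:
    """'activating' for the experimentally validated set, 'other' otherwise."""
    m = _PROTEIN_CHANGE_RE.match(protein_change.strip())
    if not m:
        raise ValueError(f"unparseable protein change {protein_change!r}")
    key = "".join(m.groups())
    return "activating" if key in ACTIVATING_HER2_MUTATIONS else "other"


def _round_half_away(x: float, decimals: int = 0) -> float:
    factor = 10**decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def subtype_crosstab(
    her2a: pd.Series | list,
    samples: SampleTable | pd.Series | list,
    pooled: list | None = None,
) -> pd.DataFrame:
    """Counts and integer percentages of amplified tumors per subtype.

    ``her2a`` is a boolean vector (or list of vectors with ``pooled`` cohort
    subtype vectors to pool across cohorts); percentages are of the amplified
    total, rounded half away from zero.
    """
    if pooled is not None:
        her2a = pd.concat([pd.Series(h).reset_index(drop=True) for h in her2a], ignore_index=True)
        subtypes = pd.concat(
            [pd.Series(s).reset_index(drop=True) for s in pooled], ignore_index=True
        )
    else:
        her2a = pd.Series(her2a)
        if isinstance(samples, SampleTable):
            subtypes = samples.df["subtype"].reindex(her2a.index)
        else:
            subtypes = pd.Series(samples)
            if isinstance(her2a.index, pd.RangeIndex):
                subtypes = subtypes.reset_index(drop=True)
    mask = her2a.fillna(False).astype(bool).to_numpy()
    sub = subtypes[mask]
    sub = sub[sub.notna() & (sub != "NA")]
    if len(sub) == 0:
        raise ValidationError("no amplified samples with subtype labels")
    counts = sub.value_counts()
    total = int(counts.sum())
    pct = counts.apply(lambda k: int(_round_half_away(100.0 * k / total)))
    return pd.DataFrame({"count": counts, "percent": pct})
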