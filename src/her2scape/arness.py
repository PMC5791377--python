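"""AR-ness signature construction and scoring of ER-negative tumors.

The AR-ness score summarizes androgen-receptor transcriptional activity in a
single sample: the mean z-scored expression of androgen-induced (positive)
signature genes minus the mean z-scored expression of androgen-suppressed
(negative) genes. Z-scoring is done across the ER- tumors of one cohort
(never pooled across cohorts), with the n-1 standard-deviation denominator.
A strictly positive score flags a tumor as AR-driven; a score of exactly
zero is called negative.

Signature genes on the anchor chromosome (17 by default) are excluded so
that the score cannot be confounded by HER2-amplicon dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort_io import ExpressionTable, GeneAnnotation, SampleTable, ValidationError, warn


@dataclass
class SignatureDefinition:
    """Positive (androgen-induced) and negative (androgen-suppressed) gene sets."""

    positive_genes: set
    negative_genes: set
    provenance: tuple = ()
    excluded_chromosome: str | None = "17"

    def __post_init__(self) -> None:
        overlap = self.positive_genes & self.negative_genes
        if overlap:
            raise ValidationError(
                f"signature genes in both positive and negative sets: {sorted(overlap)}"
            )
        if not self.positive_genes:
            raise ValidationError("positive signature gene set is empty")
        if not self.negative_genes:
            raise ValidationError("negative signature gene set is empty")


@dataclass
class ARnessResult:
    """Per-sample AR-ness scores for the ER- tumors of one cohort."""

    scores: pd.Series  # ER- samples only
    ar_driven: pd.Series  # score > 0, strict
    n_pos_used: int
    n_neg_used: int
    positive_used: list = field(default_factory=list)
    negative_used: list = field(default_factory=list)


def build_signature(
    gene_sets: dict,
    positive_source_sets: list,
    negative_source_set: str,
    genes: GeneAnnotation | None = None,
    min_membership: int = 2,
    exclude_chromosome: str | None = "17",
) -> SignatureDefinition:
    """Assemble a signature from GMT gene sets.

    Positive genes are those present in at least ``min_membership`` of the
    positive source sets; negative genes come from the single negative source
    set. Genes on ``exclude_chromosome`` (resolved through ``genes`` when
    given) and genes landing in both lists are dropped, the latter from both
    sides with a warning.
    """
    for name in list(positive_source_sets) + [negative_source_set]:
        if name not in gene_sets:
            raise KeyError(
                f"gene set {name!r} not found; available: {sorted(gene_sets)}"
            )
    counts: dict = {}
    for name in positive_source_sets:
        for g in gene_sets[name]:
            counts[g] = counts.get(g, 0) + 1
    positive = {g for g, c in counts.items() if c >= min_membership}
    negative = set(gene_sets[negative_source_set])

    if exclude_chromosome is not None and genes is not None:
        on_excl = set(genes.df.index[genes.df["chrom"] == str(exclude_chromosome)]) | set(
            genes.df.loc[genes.df["chrom"] == str(exclude_chromosome), "symbol"]
        )
        positive -= on_excl
        negative -= on_excl

    both = positive & negative
    if both:
        warn(f"dropping genes present in both positive and negative sources: {sorted(both)}")
        positive -= both
        negative -= both

    return SignatureDefinition(
        positive_genes=positive,
        negative_genes=negative,
        provenance=tuple(positive_source_sets) + (negative_source_set,),
        excluded_chromosome=exclude_chromosome,
    )


def zscore_within_group(expr: ExpressionTable, sample_mask: pd.Series) -> pd.DataFrame:
    """Z-score each gene across the masked samples (n-1 sd denominator).

    Only masked columns are returned. Genes with zero variance within the
    mask are dropped with a warning rather than propagating NaN.
    """
    cols = expr.values.columns[np.asarray(sample_mask, dtype=bool)]
    if len(cols) < 3:
        raise ValidationError("zscore_within_group needs at least 3 masked samples")
    sub = expr.values[cols]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warn(f"dropping {int((~keep).sum())} zero-variance gene(s) from z-scoring")
    sub = sub.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)


def arness_scores(
    expr: ExpressionTable,
    samples: SampleTable,
    signature: SignatureDefinition,
) -> ARnessResult:
    """Score the ER- tumors of one cohort for AR-driven transcriptional state."""
    meta = samples.df.reindex(expr.values.columns)
    er_neg = (meta["er_ihc"] == "neg").fillna(False)
    if not er_neg.any():
        raise ValidationError("no ER- samples in cohort")

    z = zscore_within_group(expr, er_neg)
    pos = sorted(g for g in signature.positive_genes if g in z.index)
    neg = sorted(g for g in signature.negative_genes if g in z.index)
    if not pos or not neg:
        raise ValidationError(
            "signature genes missing from the expression platform "
            f"(positive present: {len(pos)}, negative present: {len(neg)})"
        )
    n_total = len(signature.positive_genes) + len(signature.negative_genes)
    if len(pos) + len(neg) < n_total:
        warn(
            f"{len(pos) + len(neg)} of {n_total} signature genes available on this platform"
        )

    scores = z.loc[pos].mean(axis=0) - z.loc[neg].mean(axis=0)
    return ARnessResult(
        scores=scores,
        ar_driven=scores > 0,
        n_pos_used=len(pos),
        n_neg_used=len(neg),
        positive_used=pos,
        negative_used=neg,
    )


def load_default_signature() -> SignatureDefinition:
    """Load the packaged default signature file.

    The bundled gene list is a synthetic stand-in with the published
    signature's structure (14 androgen-induced and 31 androgen-suppressed
    genes, none on chromosome 17); for real cohorts rebuild the signature
    from MSigDB C2 GMT sources with :func:`build_signature`.
    """
    path = resources.files("her2scape.data") / "arness_signature_synthetic.tsv"
    df = pd.read_csv(path, sep="\t")
    pos = set(df.loc[df["direction"] == "pos", "gene"])
    neg = set(df.loc[df["direction"] == "neg", "gene"])
    return SignatureDefinition(
        positive_genes=pos,
        negative_genes=neg,
        provenance=("packaged synthetic default",),
        excluded_chromosome="17",
    )


def write_signature(signature: SignatureDefinition, path) -> None:
    rows = [(g, "pos") for g in sorted(signature.positive_genes)] + [
        (g, "neg") for g in sorted(signature.negative_genes)
    ]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(path, sep="\t", index=False)


def read_signature(path) -> SignatureDefinition:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "direction"} <= set(df.columns):
        raise ValidationError(f"{path}: signature file needs columns gene, direction")
    return SignatureDefinition(
        positive_genes=set(df.loc[df["direction"] == "pos", "gene"]),
        negative_genes=set(df.loc[df["direction"] == "neg", "gene"]),
        provenance=(str(path),),
    )
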