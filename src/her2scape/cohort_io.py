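"""Readers, writers and gene-level copy-number mapping shared by all pipeline stages.

All genomic coordinates are 1-based and inclusive, both in SEG files and in
the gene annotation, matching the SEG convention. Malformed input is rejected
with an error naming the offending record; nothing is silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSFORM_TAGS = ("log2_nrpkm_plus1", "log2_ratio", "log10_counts", "other")

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]
GENE_COLUMNS = ["gene_id", "symbol", "chrom", "arm", "start", "end"]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene coordinates with arm labels, totally ordered by (chrom, start).

    ``df`` is indexed by unique gene_id with columns symbol, chrom, arm,
    start, end.  ``centromeres`` maps each chromosome to the position
    separating the p and q arms (midpoint between the last p gene and the
    first q gene when both arms carry genes).
    """

    df: pd.DataFrame
    centromeres: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in GENE_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene_ids: {dups}")
        if (df["start"] > df["end"]).any():
            bad = df.index[df["start"] > df["end"]].tolist()
            raise ValidationError(f"start > end for genes: {bad}")
        bad_arm = df.index[~df["arm"].isin(["p", "q"])].tolist()
        if bad_arm:
            raise ValidationError(f"arm must be 'p' or 'q' for genes: {bad_arm}")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort")
        if not self.centromeres:
            self.centromeres = _infer_centromeres(self.df)

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    def on_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == str(chrom)]

    def arm_genes(self, chrom: str, arm: str) -> pd.Index:
        sub = self.df[(self.df["chrom"] == str(chrom)) & (self.df["arm"] == arm)]
        return sub.index

    def resolve(self, name: str) -> str:
        """Map a gene_id or symbol to a gene_id."""
        if name in self.df.index:
            return name
        hits = self.df.index[self.df["symbol"] == name]
        if len(hits) == 1:
            return hits[0]
        if len(hits) == 0:
            raise KeyError(f"gene {name!r} not found in annotation")
        raise KeyError(f"symbol {name!r} is ambiguous: {list(hits)}")


def _infer_centromeres(df: pd.DataFrame) -> dict:
    cents = {}
    for chrom, sub in df.groupby("chrom"):
        p = sub[sub["arm"] == "p"]
        q = sub[sub["arm"] == "q"]
        if len(p) and len(q):
            cents[chrom] = (int(p["end"].max()) + int(q["start"].min())) // 2
        elif len(q):
            cents[chrom] = int(q["start"].min()) - 1
        else:
            cents[chrom] = int(p["end"].max()) + 1
    return cents


@dataclass
class SegmentSet:
    """Segmented total copy number, one record per (sample, chrom, start, end).

    Segments of one sample on one chromosome must not overlap.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SEG_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"segment table missing columns: {missing}")
        df = self.df.copy()
        df["chrom"] = df["chrom"].astype(str)
        if (df["start"] > df["end"]).any():
            bad = df[df["start"] > df["end"]].iloc[0]
            raise ValidationError(
                f"segment start > end for sample {bad['sample']} on chrom {bad['chrom']}"
            )
        if (df["total_cn"] < 0).any():
            bad = df[df["total_cn"] < 0].iloc[0]
            raise ValidationError(f"negative total_cn for sample {bad['sample']}")
        for (sample, chrom), sub in df.groupby(["sample", "chrom"], sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] <= s["end"].values[:-1]).any():
                raise ValidationError(
                    f"overlapping segments for sample {sample} on chrom {chrom}"
                )
        self.df = df.sort_values(["sample", "chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def samples(self) -> list:
        return sorted(self.df["sample"].unique())

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample]


@dataclass
class CopyNumberTable:
    """Gene x sample total copy number plus per-sample ploidy.

    Ploidy lives here rather than on the sample metadata because cohorts
    profiled with targeted CN panels have no ploidy estimate; such samples
    carry NaN ploidy and ploidy-dependent calls become NA downstream.
    """

    values: pd.DataFrame  # genes x samples, NaN where no segment overlaps
    ploidy: pd.Series | None = None  # per sample, NaN allowed
    sample_quality: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValidationError("copy number values must be >= 0")
        if self.ploidy is not None:
            self.ploidy = self.ploidy.reindex(self.values.columns)
            known = self.ploidy.dropna()
            if (known <= 0).any():
                bad = known.index[known <= 0].tolist()
                raise ValidationError(f"ploidy must be > 0, offending samples: {bad}")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class ExpressionTable:
    """Gene x sample log-scale expression with a declared transform tag."""

    values: pd.DataFrame
    transform_tag: str = "other"

    def __post_init__(self) -> None:
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValidationError(
                f"unknown transform_tag {self.transform_tag!r}; expected one of {TRANSFORM_TAGS}"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")


SUBTYPES = ("LumA", "LumB", "Basal", "HER2E", "Normal-like")


@dataclass
class SampleTable:
    """Per-sample metadata: cohort, cancer type, tissue, subtype and IHC labels."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise FormatError("sample table requires a sample_id column")
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample_ids: {dups}")
        if "tissue" not in df.columns or df["tissue"].isna().any():
            raise ValidationError("tissue must be set for every sample")
        self.df = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def tumors(self) -> pd.Index:
        return self.df.index[self.df["tissue"] == "tumor"]

    def normals(self) -> pd.Index:
        return self.df.index[self.df["tissue"] == "normal"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_seg(path) -> SegmentSet:
    """Read a tab-delimited SEG file (header: sample chrom start end total_cn).

    Coordinates are 1-based inclusive. Overlapping segments within one
    sample/chromosome raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing SEG columns {missing}")
    for col in ("start", "end"):
        if len(df) == 0:
            df[col] = df[col].astype(int)
        elif not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"{path}: column {col} must be integer")
    if df["total_cn"].isna().any():
        raise FormatError(f"{path}: non-numeric or missing total_cn values")
    return SegmentSet(df[SEG_COLUMNS])


def write_seg(segments: SegmentSet, path) -> None:
    segments.df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene annotation columns {missing}")
    return GeneAnnotation(df.set_index("gene_id"))


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    genes.df.reset_index().to_csv(path, sep="\t", index=False)


def read_matrix(path, transform_tag: str = "other") -> ExpressionTable:
    """Read a gene x sample TSV matrix; round-trips bit-exactly with write_matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicated gene rows {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise FormatError(
                f"{path}: non-numeric cell(s) in column {col!r}, row(s) {bad_rows[:5]}"
            )
    return ExpressionTable(df, transform_tag=transform_tag)


def write_matrix(table: ExpressionTable | pd.DataFrame, path) -> None:
    df = table.values if isinstance(table, ExpressionTable) else table
    # 17 significant digits round-trip IEEE doubles exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_numeric_matrix(path) -> pd.DataFrame:
    """Like read_matrix but returns a bare DataFrame (methylation, protein...)."""
    return read_matrix(path, transform_tag="other").values


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: sample table requires a sample_id column")
    return SampleTable(df.set_index("sample_id"))


def write_sample_table(samples: SampleTable, path) -> None:
    samples.df.reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            genes = [g for g in parts[2:] if g]
            sets[name] = set(genes)
    return sets


# ---------------------------------------------------------------------------
# segment -> gene mapping
# ---------------------------------------------------------------------------


def segments_to_gene_cn(
    segments: SegmentSet,
    genes: GeneAnnotation,
    ploidy_map: dict | pd.Series | None = None,
) -> CopyNumberTable:
    """Project segmented CN onto genes as the bp-length-weighted mean.

    A gene's value for a sample is the mean of total_cn over the segments it
    overlaps, weighted by the overlapping base-pair count; genes with no
    overlapping segment get NaN (excluded downstream, never imputed). Samples
    absent from ``ploidy_map`` get NaN ploidy rather than an error, so that
    cohorts without ploidy estimates flow through.
    """
    gene_df = genes.df
    samples = segments.samples
    out = np.full((len(gene_df), len(samples)), np.nan)
    gene_pos = {g: i for i, g in enumerate(gene_df.index)}

    by_chrom_genes = {chrom: sub for chrom, sub in gene_df.groupby("chrom")}
    for j, sample in enumerate(samples):
        seg = segments.for_sample(sample)
        for chrom, seg_sub in seg.groupby("chrom"):
            gsub = by_chrom_genes.get(chrom)
            if gsub is None:
                continue
            s_start = seg_sub["start"].to_numpy()
            s_end = seg_sub["end"].to_numpy()
            s_cn = seg_sub["total_cn"].to_numpy(dtype=float)
            g_start = gsub["start"].to_numpy()
            g_end = gsub["end"].to_numpy()
            # overlap length of each gene with each segment (genes are few per chrom)
            ov = np.minimum(g_end[:, None], s_end[None, :]) - np.maximum(
                g_start[:, None], s_start[None, :]
            ) + 1
            ov = np.clip(ov, 0, None).astype(float)
            tot = ov.sum(axis=1)
            with np.errstate(invalid="ignore"):
                vals = (ov @ s_cn) / tot
            rows = [gene_pos[g] for g in gsub.index]
            mask = tot > 0
            for r, v, m in zip(rows, vals, mask):
                if m:
                    out[r, j] = v

    values = pd.DataFrame(out, index=gene_df.index, columns=samples)
    ploidy = None
    if ploidy_map is not None:
        ploidy = pd.Series(ploidy_map, dtype=float).reindex(samples)
    return CopyNumberTable(values=values, ploidy=ploidy)


def genome_mean_cn(segments: SegmentSet) -> pd.Series:
    """Per-sample length-weighted mean CN over all segments (a ploidy estimate)."""
    df = segments.df
    length = (df["end"] - df["start"] + 1).astype(float)
    weighted = df["total_cn"] * length
    grp = df.assign(_w=weighted, _l=length).groupby("sample")
    return grp["_w"].sum() / grp["_l"].sum()


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=2)
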