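"""Synthetic multi-omics cohort generator with ground-truth labels.

Generates a miniature cohort carrying the structures the pipeline is built to
detect: per-tumor ploidy variation, a focal amplicon around an anchor gene
(ERBB2 analogue) with a fixed core and variable broad breakpoints, arm-level
gains of the anchor's q arm, chromosomal-instability heterogeneity, copy-
dosage expression response, bimodal anchor-gene expression, subtype programs,
an androgen-receptor transcriptional program in a subset of ER-negative
tumors, germline copy-number artifacts in normals, and hypomethylation-
coupled regional overexpression in rare non-amplified tumors.

All randomness flows from a single seed through one generator, so identical
config + seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arness import SignatureDefinition
from .cohort_io import (
    CopyNumberTable,
    ExpressionTable,
    GeneAnnotation,
    SampleTable,
    SegmentSet,
    segments_to_gene_cn,
    warn,
)

# genes placed contiguously on the q arm of the anchor chromosome, in their
# physical 17q12-21 order; the amplicon core runs PNMT..GRB7 and the broad
# amplicon CDK12..CASC3
NAMED_Q_GENES = (
    "MED1",
    "CDK12",
    "PNMT",
    "PGAP3",
    "ERBB2",
    "MIEN1",
    "GRB7",
    "PSMD3",
    "NR1D1",
    "CASC3",
    "TOP2A",
)
CORE_GENES = ("PNMT", "PGAP3", "ERBB2", "MIEN1", "GRB7")
BROAD_GENES = ("CDK12",) + CORE_GENES + ("PSMD3", "NR1D1", "CASC3")
NEIGHBOR_GENES = ("PGAP3", "MIEN1", "GRB7")
DISTAL_GENES = ("MED1", "CDK12", "NR1D1", "TOP2A")
REGIONAL_GENES = ("ERBB2",) + NEIGHBOR_GENES

GENE_SPACING = 100_000
GENE_LENGTH = 20_000
ANCHOR_CHROM = "17"


@dataclass
class SimulationConfig:
    """Knobs for the cohort generator; defaults emulate a breast-like cohort.

    Fractions are planting probabilities per sample; effect sizes are on the
    log2 expression scale. ``ar_effect`` equals one default noise standard
    deviation, ``oe_shift`` and ``methylation_delta`` are strong shifts so the
    planted events are unambiguous at the default noise level.
    """

    n_tumors: int = 500
    n_normals: int = 60
    n_chromosomes: int = 5
    genes_per_chromosome: int = 60

    her2a_fraction: float = 0.12
    ploidy_weights: tuple = (0.65, 0.35)
    ploidy_means: tuple = (2.0, 3.6)
    ploidy_sds: tuple = (0.08, 0.25)
    ploidy_range: tuple = (1.8, 4.5)

    # amplicon: total CN = max(5.2, 2*ploidy*factor), capped
    amplicon_factor_range: tuple = (1.05, 2.5)
    amplicon_cn_max: float = 20.0
    broad_extension_prob: float = 0.7
    breakpoint_dispersion: float = 0.3  # P(extend >= 1 gene beyond the broad span)

    arm_gain_fraction: float = 0.15
    arm_gain_rel_range: tuple = (2.5, 3.2)  # gain level relative to diploid
    cin_rate: float = 2.0  # expected extra breakpoints per chromosome
    cin_jitter_range: tuple = (0.3, 1.2)

    dosage_beta: float = 1.0
    anchor_beta: float = 2.0  # ERBB2 dosage slope; amplified tumors express
    # the anchor well above pure dosage, giving the bimodal pattern real
    # cohorts show on the log scale
    noise_sd: float = 0.5
    cn_noise_sd: float = 0.0  # measurement noise added to the gene CN table

    subtype_proportions: dict = field(
        default_factory=lambda: {"LumA": 0.45, "LumB": 0.2, "Basal": 0.2, "HER2E": 0.15}
    )
    subtype_effect: float = 1.0
    subtype_program_size: int = 12
    er_neg_prob_by_subtype: dict = field(
        default_factory=lambda: {"LumA": 0.03, "LumB": 0.08, "Basal": 0.95, "HER2E": 0.6}
    )
    ar_driven_fraction: float = 0.35  # among ER- tumors
    ar_effect: float = 0.5  # log2 units (= 1 default noise sd)
    n_signature_pos: int = 14
    n_signature_neg: int = 31

    regional_control_fraction: float = 0.04  # among non-amplified tumors
    oe_shift: float = 2.5
    methylation_delta: float = 2.5
    meth_baseline_sd: float = 0.4

    germline_artifact_prevalence: float = 0.08
    germline_loci: tuple = ((ANCHOR_CHROM, 3, 2, 1.3), (ANCHOR_CHROM, -6, 2, 2.6))

    # trans co-amplified region: (chrom, first gene index, gene count) amplified
    # (relcn >= 4) in a fraction of amplified vs non-amplified tumors
    coamp_region: tuple | None = ("2", 20, 3)
    coamp_p_her2a: float = 0.30
    coamp_p_other: float = 0.02

    seed: int = 0

    def validate(self) -> None:
        for name in (
            "her2a_fraction",
            "broad_extension_prob",
            "breakpoint_dispersion",
            "arm_gain_fraction",
            "ar_driven_fraction",
            "regional_control_fraction",
            "germline_artifact_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if self.genes_per_chromosome < len(NAMED_Q_GENES) + 10:
            raise ValueError(
                f"genes_per_chromosome must be >= {len(NAMED_Q_GENES) + 10} to place "
                "the named anchor neighborhood"
            )


@dataclass
class TruthLabels:
    """Planted ground truth, consistent with the generated matrices by construction."""

    samples: pd.DataFrame  # per tumor: her2a, q17_group, ar_driven, regional_control, ...
    genes: pd.DataFrame  # per gene: dosage_responsive, signature_pos/neg, amplicon flags
    amplicon_core_genes: list
    amplicon_broad_genes: list
    coamp_region_genes: list
    hypomethylated_probes: list
    germline_artifact_genes: list


@dataclass
class Cohort:
    genes: GeneAnnotation
    segments: SegmentSet  # tumors and normals
    cn: CopyNumberTable  # tumors, with measurement noise if configured
    cn_normals: CopyNumberTable
    expr: ExpressionTable  # tumors
    methylation: pd.DataFrame  # probes x tumors (M-values)
    probe_map: pd.DataFrame  # probe -> gene, dist_to_tss, in_gene_body
    samples: SampleTable  # tumors and normals
    truth: TruthLabels
    signature: SignatureDefinition
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig, seed: int | None = None) -> GeneAnnotation:
    """Lay out the synthetic genome: ``n_chromosomes`` chromosomes of evenly
    spaced genes, the last one an anchor-chromosome analogue (labelled "17")
    whose q arm carries ERBB2 and its named neighbors contiguously in
    physical order. Deterministic given the config (the seed is accepted for
    interface symmetry; gene layout involves no random draws)."""
    config.validate()
    gpc = config.genes_per_chromosome
    chroms = [str(i + 1) for i in range(config.n_chromosomes - 1)] + [ANCHOR_CHROM]
    rows = []
    for chrom in chroms:
        n_p = max(4, int(0.4 * gpc))
        q_named_at = n_p + 3
        for i in range(gpc):
            start = 1 + i * GENE_SPACING
            end = start + GENE_LENGTH - 1
            arm = "p" if i < n_p else "q"
            symbol = f"g{chrom}_{i:04d}"
            if chrom == ANCHOR_CHROM and q_named_at <= i < q_named_at + len(NAMED_Q_GENES):
                symbol = NAMED_Q_GENES[i - q_named_at]
            rows.append((symbol, symbol, chrom, arm, start, end))
    df = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "arm", "start", "end"])
    return GeneAnnotation(df.set_index("gene_id"))


def chromosome_length(config: SimulationConfig) -> int:
    return config.genes_per_chromosome * GENE_SPACING + GENE_SPACING // 2


# ---------------------------------------------------------------------------
# interval overlay
# ---------------------------------------------------------------------------


def _overlay(intervals, start, end, cn):
    """Replace [start, end] within a list of (s, e, cn) intervals by ``cn``."""
    out = []
    for s, e, c in intervals:
        if e < start or s > end:
            out.append((s, e, c))
            continue
        if s < start:
            out.append((s, start - 1, c))
        if e > end:
            out.append((end + 1, e, c))
    out.append((start, end, cn))
    out.sort()
    return out


def _clip_overlay(intervals, start, end, cn, lo, hi):
    start = max(lo, start)
    end = min(hi, end)
    if start > end:
        return intervals
    return _overlay(intervals, start, end, cn)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Generate segments, copy number, expression, methylation, metadata and
    truth labels for one cohort. See the module docstring for the structures
    planted; the expression model is

        expr[g, s] = mu_g + beta_g * log2(max(relcn[g, s], 0.5) / 2)
                     + subtype effect + AR program + regional shift + noise

    with relcn the ploidy-corrected copy number (diploid = 2)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = generate_genome(config)
    gene_df = genes.df
    chrom_len = chromosome_length(config)
    chroms = sorted(gene_df["chrom"].unique(), key=lambda c: (len(c), c))

    n_t = config.n_tumors
    tumor_ids = [f"T{i:04d}" for i in range(n_t)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normals)]

    # --- per-sample states -------------------------------------------------
    comp = rng.choice(len(config.ploidy_weights), size=n_t, p=config.ploidy_weights)
    ploidy = np.clip(
        rng.normal(np.array(config.ploidy_means)[comp], np.array(config.ploidy_sds)[comp]),
        *config.ploidy_range,
    )

    subtype_names = list(config.subtype_proportions)
    props = np.array([config.subtype_proportions[s] for s in subtype_names], dtype=float)
    props = props / props.sum()
    subtype = rng.choice(subtype_names, size=n_t, p=props)
    er_neg = rng.random(n_t) < np.array(
        [config.er_neg_prob_by_subtype.get(s, 0.1) for s in subtype]
    )

    if config.her2a_fraction * n_t < 1:
        warn("her2a_fraction * n_tumors < 1; expecting zero amplified samples")
    her2a = rng.random(n_t) < config.her2a_fraction
    arm_event = rng.random(n_t) < config.arm_gain_fraction
    arm_level = rng.uniform(*config.arm_gain_rel_range, size=n_t)  # relative to diploid
    ar_driven = er_neg & (rng.random(n_t) < config.ar_driven_fraction)
    regional = (~her2a) & (rng.random(n_t) < config.regional_control_fraction)

    # broad amplicon extension: a fixed fraction of amplified samples (chosen
    # at random but with exact count) carry the broad span, the rest only the
    # core; broad carriers may extend a few genes further per side
    her2a_idx = np.flatnonzero(her2a)
    n_broad = int(round(config.broad_extension_prob * len(her2a_idx)))
    broad_carriers = set(rng.permutation(her2a_idx)[:n_broad].tolist())

    amp_factor = rng.uniform(*config.amplicon_factor_range, size=n_t)
    cin_mult = rng.lognormal(mean=0.0, sigma=0.5, size=n_t) * np.where(her2a, 1.5, 1.0)
    coamp_carrier = np.zeros(n_t, dtype=bool)
    coamp_span = None
    coamp_gene_ids: list = []
    if config.coamp_region is not None:
        co_chrom, co_idx, co_n = config.coamp_region
        co_sub = gene_df[gene_df["chrom"] == str(co_chrom)].sort_values("start")
        co_run = co_sub.iloc[co_idx : co_idx + co_n]
        coamp_gene_ids = list(co_run.index)
        coamp_span = (str(co_chrom), int(co_run["start"].min()), int(co_run["end"].max()))
        p = np.where(her2a, config.coamp_p_her2a, config.coamp_p_other)
        coamp_carrier = rng.random(n_t) < p

    anchor17 = gene_df[gene_df["chrom"] == ANCHOR_CHROM]
    core_rows = anchor17.loc[list(CORE_GENES)].sort_values("start")
    broad_rows = anchor17.loc[list(BROAD_GENES)].sort_values("start")
    core_span = (int(core_rows["start"].min()), int(core_rows["end"].max()))
    q_start_17 = int(anchor17[anchor17["arm"] == "q"]["start"].min())
    anchor_guard = (core_span[0] - GENE_SPACING // 2, core_span[1] + GENE_SPACING // 2)
    genes_17_sorted = anchor17.sort_values("start")
    pos_in_17 = {g: i for i, g in enumerate(genes_17_sorted.index)}
    broad_lo = pos_in_17[broad_rows.index[0]]
    broad_hi = pos_in_17[broad_rows.index[-1]]

    # --- segments ----------------------------------------------------------
    seg_rows = []
    for i, sid in enumerate(tumor_ids):
        for chrom in chroms:
            intervals = [(1, chrom_len, float(ploidy[i]))]
            if chrom == ANCHOR_CHROM and arm_event[i]:
                gain_cn = arm_level[i] * ploidy[i] / 2.0
                intervals = _overlay(intervals, q_start_17 - GENE_SPACING // 4, chrom_len, gain_cn)
            n_breaks = rng.poisson(config.cin_rate * cin_mult[i])
            for _ in range(n_breaks):
                for _try in range(4):
                    s = int(rng.integers(1, chrom_len - 500_000))
                    e = s + int(rng.integers(300_000, 3_000_000))
                    e = min(e, chrom_len)
                    # keep the anchor neighborhood of non-amplified tumors
                    # free of instability jitter so their amplification status
                    # is unambiguous by construction
                    if chrom == ANCHOR_CHROM and not her2a[i]:
                        if not (e < anchor_guard[0] or s > anchor_guard[1]):
                            continue
                    break
                else:
                    continue
                base = intervals[0][2]
                jit = rng.uniform(*config.cin_jitter_range) * rng.choice([-1.0, 1.0])
                cn = max(0.2, float(ploidy[i]) + jit)
                if chrom == ANCHOR_CHROM and not her2a[i]:
                    cn = min(cn, 1.9 * float(ploidy[i]))
                intervals = _overlay(intervals, s, e, cn)
            if coamp_span is not None and chrom == coamp_span[0] and coamp_carrier[i]:
                co_cn = min(config.amplicon_cn_max, 2.2 * ploidy[i])
                intervals = _clip_overlay(
                    intervals,
                    coamp_span[1] - GENE_SPACING // 4,
                    coamp_span[2] + GENE_SPACING // 4,
                    co_cn,
                    1,
                    chrom_len,
                )
            if chrom == ANCHOR_CHROM and her2a[i]:
                lo_g, hi_g = pos_in_17[core_rows.index[0]], pos_in_17[core_rows.index[-1]]
                if i in broad_carriers:
                    lo_g, hi_g = broad_lo, broad_hi
                    ext = rng.geometric(1.0 - config.breakpoint_dispersion) - 1
                    ext2 = rng.geometric(1.0 - config.breakpoint_dispersion) - 1
                    lo_g = max(0, lo_g - int(ext))
                    hi_g = min(len(genes_17_sorted) - 1, hi_g + int(ext2))
                amp_start = int(genes_17_sorted.iloc[lo_g]["start"] - rng.uniform(0, GENE_SPACING * 0.4))
                amp_end = int(genes_17_sorted.iloc[hi_g]["end"] + rng.uniform(0, GENE_SPACING * 0.4))
                amp_cn = min(config.amplicon_cn_max, max(5.2, 2.0 * ploidy[i] * amp_factor[i]))
                intervals = _clip_overlay(intervals, amp_start, amp_end, amp_cn, 1, chrom_len)
            for s, e, c in sorted(intervals):
                seg_rows.append((sid, chrom, s, e, c))

    germline = []  # (chrom, start, end, cn, gene_ids)
    for chrom, idx, n_genes, cn in config.germline_loci:
        sub = gene_df[gene_df["chrom"] == str(chrom)].sort_values("start")
        idx = idx if idx >= 0 else len(sub) + idx
        run = sub.iloc[idx : idx + n_genes]
        germline.append((str(chrom), int(run["start"].min()), int(run["end"].max()), float(cn), list(run.index)))

    for sid in normal_ids:
        carries = rng.random() < config.germline_artifact_prevalence
        for chrom in chroms:
            intervals = [(1, chrom_len, 2.0)]
            if carries:
                for gc, gs, ge, gcn, _ in germline:
                    if gc == chrom:
                        intervals = _overlay(intervals, gs, ge, gcn)
            for s, e, c in sorted(intervals):
                seg_rows.append((sid, chrom, s, e, c))

    segments = SegmentSet(
        pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end", "total_cn"])
    )

    # --- gene-level CN -----------------------------------------------------
    ploidy_map = {sid: float(p) for sid, p in zip(tumor_ids, ploidy)}
    tumor_segments = SegmentSet(segments.df[segments.df["sample"].isin(tumor_ids)])
    normal_segments = SegmentSet(segments.df[segments.df["sample"].isin(normal_ids)])
    cn_clean = segments_to_gene_cn(tumor_segments, genes, ploidy_map)
    cn_normals = segments_to_gene_cn(
        normal_segments, genes, {sid: 2.0 for sid in normal_ids}
    )
    cn_values = cn_clean.values.copy()
    if config.cn_noise_sd > 0:
        cn_values = (
            cn_values + rng.normal(0.0, config.cn_noise_sd, size=cn_values.shape)
        ).clip(lower=0.0)
    cn = CopyNumberTable(values=cn_values, ploidy=cn_clean.ploidy)

    # --- gene roles --------------------------------------------------------
    non17 = [g for g in gene_df.index if gene_df.loc[g, "chrom"] != ANCHOR_CHROM]
    pool = list(rng.permutation(non17))
    sig_pos = sorted(pool[: config.n_signature_pos])
    sig_neg = sorted(pool[config.n_signature_pos : config.n_signature_pos + config.n_signature_neg])
    off = config.n_signature_pos + config.n_signature_neg
    programs = {}
    for st in subtype_names:
        programs[st] = pool[off : off + config.subtype_program_size]
        off += config.subtype_program_size
    signature = SignatureDefinition(
        positive_genes=set(sig_pos),
        negative_genes=set(sig_neg),
        provenance=("synthetic_cohort",),
        excluded_chromosome=ANCHOR_CHROM,
    )

    dosage_genes = set(BROAD_GENES) | set(CORE_GENES)
    beta = pd.Series(0.0, index=gene_df.index)
    beta[list(dosage_genes)] = config.dosage_beta
    beta["ERBB2"] = config.anchor_beta

    # --- expression --------------------------------------------------------
    mu = pd.Series(rng.normal(6.5, 0.8, size=len(gene_df)), index=gene_df.index)
    rel = 2.0 * cn_clean.values.div(pd.Series(ploidy_map), axis=1)
    rel = rel.fillna(2.0).clip(lower=0.5)
    expr = mu.values[:, None] + beta.values[:, None] * np.log2(rel.values / 2.0)
    expr = pd.DataFrame(expr, index=gene_df.index, columns=tumor_ids)

    for st in subtype_names:
        mask = subtype == st
        expr.loc[programs[st], mask] += config.subtype_effect
    expr.loc[sig_pos, ar_driven] += config.ar_effect
    expr.loc[sig_neg, ar_driven] -= config.ar_effect
    expr.loc[list(REGIONAL_GENES), regional] += config.oe_shift
    # two luminal-marker stand-ins off the anchor chromosome track ER status
    esr1, pgr = pool[off], pool[off + 1]
    expr.loc[esr1, ~er_neg] += 2.5
    expr.loc[pgr, ~er_neg] += 2.0
    if config.noise_sd > 0:
        expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
    expression = ExpressionTable(expr, transform_tag="log2_nrpkm_plus1")

    # --- methylation -------------------------------------------------------
    probe_rows = []
    for g in REGIONAL_GENES:
        for k, (dist, body) in enumerate([(-1500, False), (200, True), (1000, True)]):
            probe_rows.append((f"cg_{g}_{k}", g, dist, body, True))
        probe_rows.append((f"cg_{g}_far", g, -5000, False, False))
    for g in DISTAL_GENES:
        for k, (dist, body) in enumerate([(-800, False), (500, True)]):
            probe_rows.append((f"cg_{g}_{k}", g, dist, body, False))
    probe_map = pd.DataFrame(
        probe_rows, columns=["probe", "gene", "dist_to_tss", "in_gene_body", "shifted"]
    ).set_index("probe")
    m_base = rng.normal(1.0, config.meth_baseline_sd, size=len(probe_map))
    meth = np.tile(m_base[:, None], (1, n_t))
    shifted_probes = probe_map.index[probe_map["shifted"]].tolist()
    meth = pd.DataFrame(meth, index=probe_map.index, columns=tumor_ids)
    meth.loc[shifted_probes, regional] -= config.methylation_delta
    if config.noise_sd > 0:
        meth += rng.normal(0.0, config.noise_sd, size=meth.shape)
    probe_map = probe_map.drop(columns=["shifted"])

    # --- metadata ----------------------------------------------------------
    prolif_shift = {"Basal": 1.0, "LumB": 0.7, "HER2E": 0.5, "LumA": -0.5}
    prolif = rng.normal(0.0, 1.0, size=n_t) + np.array(
        [prolif_shift.get(s, 0.0) for s in subtype]
    )
    sample_df = pd.DataFrame(
        {
            "sample_id": tumor_ids + normal_ids,
            "cohort": "synthetic",
            "cancer_type": "BRCA",
            "tissue": ["tumor"] * n_t + ["normal"] * config.n_normals,
            "subtype": list(subtype) + ["NA"] * config.n_normals,
            "er_ihc": ["neg" if e else "pos" for e in er_neg] + ["NA"] * config.n_normals,
            "pr_ihc": ["neg" if e else "pos" for e in er_neg] + ["NA"] * config.n_normals,
            "her2_clinical": ["pos" if h else "neg" for h in her2a]
            + ["NA"] * config.n_normals,
            "proliferation_score": list(prolif) + [np.nan] * config.n_normals,
        }
    ).set_index("sample_id")
    samples = SampleTable(sample_df)

    # --- truth -------------------------------------------------------------
    q_gene_ids = genes.arm_genes(ANCHOR_CHROM, "q")
    q_cn = cn_clean.values.loc[q_gene_ids]
    q17 = []
    for sid in tumor_ids:
        v = q_cn[sid].dropna().to_numpy()
        f_amp = (v >= 5).mean()
        f_gain = ((v >= 2.5) & (v < 5)).mean()
        f_dip = (v < 2.5).mean()
        if f_amp >= 0.8:
            q17.append("arm_amp")
        elif f_gain >= 0.8:
            q17.append("gain")
        elif f_dip > 0.5:
            q17.append("diploid")
        else:
            q17.append(["diploid", "gain", "arm_amp"][int(np.argmax([f_dip, f_gain, f_amp]))])

    truth_samples = pd.DataFrame(
        {
            "her2a": her2a,
            "q17_group": q17,
            "ar_driven": ar_driven,
            "regional_control": regional,
            "er_neg": er_neg,
            "subtype": subtype,
            "ploidy": ploidy,
            "broad_carrier": [i in broad_carriers for i in range(n_t)],
            "coamp_carrier": coamp_carrier,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    truth_genes = pd.DataFrame(
        {
            "dosage_responsive": [g in dosage_genes for g in gene_df.index],
            "signature_pos": [g in set(sig_pos) for g in gene_df.index],
            "signature_neg": [g in set(sig_neg) for g in gene_df.index],
            "amplicon_core": [g in set(CORE_GENES) for g in gene_df.index],
            "amplicon_broad": [g in set(BROAD_GENES) for g in gene_df.index],
            "coamp_region": [g in set(coamp_gene_ids) for g in gene_df.index],
        },
        index=gene_df.index,
    )
    truth = TruthLabels(
        samples=truth_samples,
        genes=truth_genes,
        amplicon_core_genes=list(core_rows.index),
        amplicon_broad_genes=list(broad_rows.index),
        coamp_region_genes=coamp_gene_ids,
        hypomethylated_probes=shifted_probes,
        germline_artifact_genes=[g for *_, ids in germline for g in ids],
    )

    return Cohort(
        genes=genes,
        segments=segments,
        cn=cn,
        cn_normals=cn_normals,
        expr=expression,
        methylation=meth,
        probe_map=probe_map,
        samples=samples,
        truth=truth,
        signature=signature,
        config=config,
    )


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML/JSON config files)."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return SimulationConfig(**kwargs)
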