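"""Fold changes, covariate-adjusted DGE, regional control and prevalence arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from her2scape import expression_effects as ee
from her2scape.cohort_io import ExpressionTable, ValidationError
from her2scape.her2a_calling import call_her2a, call_overexpression, set_overexpression

from conftest import make_cn, make_genes


def _expr(data, samples=None):
    df = pd.DataFrame(data).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return ExpressionTable(df.astype(float), transform_tag="other")


class TestFoldChange:
    def test_two_unit_log_difference_is_fourfold(self):
        expr = _expr({"g": [8.0, 8.0, 6.0, 6.0]})
        a = pd.Series([True, True, False, False], index=expr.values.columns)
        assert ee.log2_fold_change(expr, a, ~a)["g"] == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        expr = _expr({"g": [5.0, 5.0, 5.0, 5.0]})
        a = pd.Series([True, False, True, False], index=expr.values.columns)
        assert ee.log2_fold_change(expr, a, ~a)["g"] == 0.0

    def test_toy_matrix_matches_hand_means(self):
        expr = _expr({"g1": [1, 2, 3, 4], "g2": [0, 0, 1, 1], "g3": [2, 2, 2, 2]})
        a = pd.Series([True, True, False, False], index=expr.values.columns)
        fc = ee.log2_fold_change(expr, a, ~a)
        assert fc.tolist() == pytest.approx([1.5 - 3.5, 0 - 1, 0])

    def test_empty_group_rejected(self):
        expr = _expr({"g": [1.0, 2.0]})
        mask = pd.Series([True, True], index=expr.values.columns)
        with pytest.raises(ValidationError):
            ee.log2_fold_change(expr, mask, ~mask)


class TestCovariateAdjustedDge:
    def test_subtype_confounded_gene_needs_adjustment(self):
        # effect injected purely through subtype: a hit without the subtype
        # covariate, not a hit with it
        rng = np.random.default_rng(0)
        n = 200
        subtype = rng.choice(["A", "B"], size=n, p=[0.5, 0.5])
        contrast = (subtype == "A") & (rng.random(n) < 0.6)  # correlated with subtype
        g = 5.0 + 2.0 * (subtype == "A") + rng.normal(0, 0.3, n)
        expr = _expr({"g": g, "null": rng.normal(0, 0.3, n)})
        cmask = pd.Series(contrast, index=expr.values.columns)
        cov = pd.DataFrame({"subtype": subtype}, index=expr.values.columns)
        raw = ee.covariate_adjusted_dge(expr, cmask)
        adj = ee.covariate_adjusted_dge(expr, cmask, cov)
        assert raw.table.loc["g", "fdr"] < 0.05 and abs(raw.table.loc["g", "log2fc"]) > 1
        assert adj.table.loc["g", "p"] > 0.01

    def test_planted_dosage_gene_recovered_with_accurate_effect(self, default_cohort):
        c = default_cohort
        calls = call_her2a(c.cn, c.genes, scheme="ploidy")
        mask = calls.df["call_ploidy"].astype(bool)
        cov = pd.DataFrame(
            {"subtype": c.truth.samples["subtype"]}, index=c.expr.values.columns
        )
        res = ee.covariate_adjusted_dge(c.expr, mask, cov)
        dosage = [g for g in c.truth.amplicon_core_genes]
        trans = c.truth.genes.index[
            ~c.truth.genes["dosage_responsive"]
            & ~c.truth.genes["signature_pos"]
            & ~c.truth.genes["signature_neg"]
        ]
        assert (res.table.loc[dosage, "fdr"] < 0.05).all()
        # planted trans genes stay quiet
        assert (res.table.loc[trans, "hit"]).mean() < 0.02

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(1)
        expr = _expr({"g": rng.normal(size=10)})
        mask = pd.Series([True] * 5 + [False] * 5, index=expr.values.columns)
        cov = pd.DataFrame(
            {"dup": mask.astype(float)}, index=expr.values.columns
        )  # identical to contrast
        with pytest.raises(ValidationError, match="dup"):
            ee.covariate_adjusted_dge(expr, mask, cov)

    def test_too_few_samples_rejected(self):
        expr = _expr({"g": [1.0, 2.0, 3.0]})
        mask = pd.Series([True, True, False], index=expr.values.columns)
        with pytest.raises(ValidationError):
            ee.covariate_adjusted_dge(expr, mask)

    def test_gene_exclusion_list_respected(self):
        rng = np.random.default_rng(2)
        expr = _expr({"keep": rng.normal(size=20), "drop": rng.normal(size=20)})
        mask = pd.Series([True] * 10 + [False] * 10, index=expr.values.columns)
        res = ee.covariate_adjusted_dge(expr, mask, exclude_genes=["drop"])
        assert list(res.table.index) == ["keep"]


class TestSelectHits:
    def _result(self, fdr, lfc):
        table = pd.DataFrame({"log2fc": [lfc], "p": [fdr], "fdr": [fdr], "hit": [False]},
                             index=["g"])
        return ee.DgeResult(table=table, covariates=[])

    def test_fdr_and_fc_both_required(self):
        assert ee.select_dge_hits(self._result(0.04, 1.1)) == ["g"]
        assert ee.select_dge_hits(self._result(0.04, 0.9)) == []
        assert ee.select_dge_hits(self._result(0.06, 1.5)) == []

    def test_negative_fold_change_counts(self):
        assert ee.select_dge_hits(self._result(0.01, -1.5)) == ["g"]

    def test_multi_cohort_at_least_one_rule(self):
        both = [self._result(0.5, 0.1), self._result(0.01, 2.0)]
        assert ee.select_dge_hits(both) == ["g"]


class TestNonAmplifiedOverexpressors:
    def test_definition_truth_table(self):
        genes = make_genes(
            [("p0", "17", "p", 1, 10), ("ERBB2", "17", "q", 100, 200)]
        )
        cn = make_cn({"ERBB2": [8.0, 2.0, 2.0], "p0": [2.0] * 3}, ploidy=[2.0] * 3)
        calls = call_her2a(cn, genes, scheme="ploidy")
        oe = pd.Series([True, True, False], index=cn.values.columns)
        set_overexpression(calls, oe)
        assert ee.find_nonamplified_overexpressors(calls) == ["S1"]

    def test_planted_regional_control_recovered_exactly(self, noiseless_cohort):
        from her2scape.her2a_calling import fit_bimodal_threshold
        from her2scape.synthetic_cohort import DISTAL_GENES, NEIGHBOR_GENES, REGIONAL_GENES

        c = noiseless_cohort
        calls = call_her2a(c.cn, c.genes, scheme="ploidy")
        fit = fit_bimodal_threshold(c.expr.values.loc["ERBB2"], seed=0)
        set_overexpression(calls, call_overexpression(c.expr, "ERBB2", fit.threshold))
        candidates = ee.find_nonamplified_overexpressors(calls)
        window = list(("MED1", "CDK12", "PNMT", "PGAP3", "ERBB2", "MIEN1",
                       "GRB7", "PSMD3", "NR1D1", "CASC3", "TOP2A"))
        rel = ee.relative_expression_to_diploid(c.expr, c.cn, c.genes, window)
        flags = ee.regional_control_flag(rel, candidates)
        recovered = set(flags.index[flags.fillna(False).astype(bool)])
        planted = set(c.truth.samples.index[c.truth.samples["regional_control"]])
        assert recovered == planted


class TestRelativeExpression:
    genes = make_genes(
        [("p0", "17", "p", 1, 10), ("ERBB2", "17", "q", 100, 200),
         ("PGAP3", "17", "q", 300, 400)]
    )

    def _tables(self):
        # 6 reference samples (anchor CN 2) and one overexpressor
        samples = [f"s{i}" for i in range(7)]
        cn_vals = {"ERBB2": [2.0] * 6 + [2.0], "PGAP3": [2.0] * 7, "p0": [2.0] * 7}
        cn = make_cn(cn_vals, ploidy=[2.0] * 7, samples=samples)
        expr = _expr({"ERBB2": [5, 5, 5, 5, 5, 5, 7], "PGAP3": [4, 4, 4, 4, 4, 4, 6]},
                     samples=samples)
        return expr, cn

    def test_reference_samples_center_at_zero(self):
        expr, cn = self._tables()
        rel = ee.relative_expression_to_diploid(expr, cn, self.genes, ["ERBB2", "PGAP3"])
        assert rel.loc["ERBB2"].iloc[:6].median() == 0.0

    def test_planted_fourfold_neighbor_shows_plus_two(self):
        expr, cn = self._tables()
        rel = ee.relative_expression_to_diploid(expr, cn, self.genes, ["ERBB2", "PGAP3"])
        assert rel.loc["PGAP3"].iloc[-1] == pytest.approx(2.0)

    def test_small_reference_stratum_skipped_with_warning(self):
        expr, cn = self._tables()
        strata = pd.Series(["tiny"] * 2 + ["big"] * 5, index=expr.values.columns)
        with pytest.warns(UserWarning, match="tiny"):
            rel = ee.relative_expression_to_diploid(
                expr, cn, self.genes, ["ERBB2"], strata=strata
            )
        assert rel.loc["ERBB2"].iloc[:2].isna().all()


class TestRegionalControlFlag:
    def _rel(self, neighbors, distals):
        rows = {g: [v] for g, v in zip(("PGAP3", "MIEN1", "GRB7"), neighbors)}
        rows |= {g: [v] for g, v in zip(("MED1", "CDK12", "NR1D1", "TOP2A"), distals)}
        return pd.DataFrame(rows, index=["S0"]).T

    def test_neighbors_up_distals_flat_is_regional(self):
        flags = ee.regional_control_flag(self._rel([2, 2, 2], [0, 0, 0, 0]), ["S0"])
        assert flags["S0"] == True  # noqa: E712

    def test_everything_elevated_is_arm_level_not_regional(self):
        flags = ee.regional_control_flag(self._rel([2, 2, 2], [2, 2, 2, 2]), ["S0"])
        assert flags["S0"] == False  # noqa: E712

    def test_flat_neighbors_not_regional(self):
        flags = ee.regional_control_flag(self._rel([0, 0, 0], [0, 0, 0, 0]), ["S0"])
        assert flags["S0"] == False  # noqa: E712

    def test_missing_neighbor_gene_gives_na(self):
        rel = self._rel([2, 2, 2], [0, 0, 0, 0]).drop(index=["PGAP3"])
        with pytest.warns(UserWarning, match="PGAP3"):
            flags = ee.regional_control_flag(rel, ["S0"])
        assert flags["S0"] is pd.NA


class TestMethylationGroupTest:
    def _inputs(self, shift, n_per_group=40, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        groups = (["HA_oe"] * n_per_group + ["HA"] * n_per_group
                  + ["nHA_oe"] * n_per_group + ["nHA"] * n_per_group)
        n = len(groups)
        samples = [f"s{i}" for i in range(n)]
        her2a = pd.Series([g.startswith("HA") for g in groups], index=samples)
        oe = pd.Series([g.endswith("oe") for g in groups], index=samples)
        probes = [f"cg{i}" for i in range(20)]
        m = rng.normal(1.0, noise, size=(20, n))
        # planted hypomethylation in the non-amplified overexpressor group
        target = (~her2a & oe).to_numpy()
        m[:5, target] += shift
        mvals = pd.DataFrame(m, index=probes, columns=samples)
        pmap = pd.DataFrame(
            {"gene": ["ERBB2"] * 20, "dist_to_tss": 100, "in_gene_body": True},
            index=pd.Index(probes, name="probe"),
        )
        return mvals, pmap, her2a, oe

    def test_planted_hypomethylation_detected(self):
        mvals, pmap, her2a, oe = self._inputs(shift=-2.0)
        out = ee.methylation_group_test(mvals, pmap, her2a, oe, fdr_cut=0.01)
        assert (out.loc[[f"cg{i}" for i in range(5)], "fdr"] < 0.01).all()

    def test_null_probes_quiet(self):
        mvals, pmap, her2a, oe = self._inputs(shift=0.0, seed=3)
        out = ee.methylation_group_test(mvals, pmap, her2a, oe, fdr_cut=0.01)
        assert not out["significant"].any()

    def test_empty_group_degrades_to_three_group_test(self):
        mvals, pmap, her2a, oe = self._inputs(shift=-2.0)
        oe[her2a.to_numpy()] = True  # HER2A non-oe group empties
        with pytest.warns(UserWarning, match="3 non-empty"):
            out = ee.methylation_group_test(mvals, pmap, her2a, oe)
        assert (out.loc[[f"cg{i}" for i in range(5)], "p"] < 0.01).all()

    def test_matches_tie_corrected_rank_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            sizes = rng.integers(5, 15, size=4)
            vals = [np.round(rng.normal(size=s), 1) for s in sizes]  # rounding forces ties
            stat, p = stats.kruskal(*vals)
            # independent rank-sum computation with tie correction
            allv = np.concatenate(vals)
            ranks = stats.rankdata(allv)
            n = len(allv)
            start, h = 0, 0.0
            for v in vals:
                r = ranks[start : start + len(v)]
                h += r.sum() ** 2 / len(v)
                start += len(v)
            h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
            _, counts = np.unique(allv, return_counts=True)
            h /= 1 - ((counts**3 - counts).sum()) / (n**3 - n)
            assert h == pytest.approx(stat)
            assert stats.chi2.sf(h, 3) == pytest.approx(p)


class TestPrevalenceArithmetic:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(106, 864, 12.3), (98, 5391, 1.8), (0, 10, 0.0), (24, 271, 8.9)],
    )
    def test_prevalence_percent(self, k, n, expected):
        assert ee.prevalence_percent(k, n) == expected

    def test_prevalence_input_validation(self):
        with pytest.raises(ValidationError):
            ee.prevalence_percent(1, 0)
        with pytest.raises(ValidationError):
            ee.prevalence_percent(5, 3)

    @pytest.mark.parametrize(
        "pct,cases,expected",
        [(12.3, 234190, 28805), (8.9, 24590, 2189), (0.0, 100000, 0)],
    )
    def test_estimate_cases(self, pct, cases, expected):
        assert ee.estimate_her2a_cases(pct, cases) == expected

    def test_estimate_negative_rejected(self):
        with pytest.raises(ValidationError):
            ee.estimate_her2a_cases(-1.0, 100)

    def test_table3_summary_with_mixed_rounding(self):
        rows = pd.DataFrame(
            {
                "cancer": ["stomach", "bladder"],
                "k": [24, 7],
                "n": [271, 168],
                "annual_cases": [24590, 74000],
                "use_unrounded": [False, True],
            }
        )
        out = ee.table3_summary(rows)
        assert out.loc[0, "estimated_her2a_cases"] == 2189
        # bladder uses the raw 7/168 fraction
        assert out.loc[1, "estimated_her2a_cases"] == 3083
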