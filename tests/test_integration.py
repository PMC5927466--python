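"""Gene-level methylation summaries, DMEG counts, odds ratio, concordance."""

import numpy as np
import pandas as pd
import pytest

from triomic import (
    DifferentialExpressionModel,
    MethylationModel,
    concordance,
    count_dmegs,
    deg_dml_association,
    generate_expression,
    generate_methylation,
    summarize_gene_methylation,
)
from triomic.integration import odds_ratio_2x2, round_percentage


def _dml_table(rows):
    """rows: (probe, gene, loc, is_dml, p_day3, delta_day3)"""
    return pd.DataFrame(
        [
            {
                "probe_id": p, "gene_id": g, "location_class": loc,
                "is_dml": dml, "p_day3": pv, "delta_day3": dv,
            }
            for p, g, loc, dml, pv, dv in rows
        ]
    ).set_index("probe_id")


def _deg_table(rows):
    """rows: (gene, is_deg, p_day3, dir_day3)"""
    return pd.DataFrame(
        [
            {"gene_id": g, "is_deg": d, "p_day3": pv, "dir_day3": dr}
            for g, d, pv, dr in rows
        ]
    ).set_index("gene_id")


class TestGeneSummaries:
    def test_single_promoter_probe(self):
        t = _dml_table([("p1", "gA", "TSS200", True, 0.01, 10.0)])
        s = summarize_gene_methylation(t, 3)
        assert s.loc["gA", "promoter_delta"] == 10.0
        assert bool(s.loc["gA", "has_promoter_dml"])

    def test_opposing_promoter_probes_average_to_zero(self):
        t = _dml_table(
            [
                ("p1", "gA", "TSS200", True, 0.01, 10.0),
                ("p2", "gA", "TSS1500", True, 0.01, -10.0),
            ]
        )
        s = summarize_gene_methylation(t, 3)
        assert s.loc["gA", "promoter_delta"] == 0.0
        assert bool(s.loc["gA", "has_promoter_dml"])

    def test_overall_averages_across_scopes(self):
        t = _dml_table(
            [
                ("p1", "gA", "TSS200", True, 0.01, 10.0),
                ("p2", "gA", "Body", True, 0.01, 30.0),
                ("p3", "gA", "5UTR", True, 0.01, 20.0),
            ]
        )
        s = summarize_gene_methylation(t, 3)
        assert s.loc["gA", "overall_delta"] == pytest.approx(20.0)
        assert s.loc["gA", "body_delta"] == pytest.approx(30.0)

    def test_non_significant_probes_ignored(self):
        t = _dml_table(
            [
                ("p1", "gA", "TSS200", True, 0.5, 10.0),  # day test ns
                ("p2", "gB", "TSS200", False, 0.01, 10.0),  # not a DML
            ]
        )
        s = summarize_gene_methylation(t, 3)
        assert len(s) == 0


class TestDMEGCounts:
    @pytest.mark.parametrize(
        "n,total,pct", [(63, 236, 27), (978, 2135, 46), (1627, 2854, 57), (184, 236, 78)]
    )
    def test_published_style_percentages(self, n, total, pct):
        assert round_percentage(n, total) == pct

    def test_counting_contract(self):
        deg = _deg_table(
            [("gA", True, 0.01, "up"), ("gB", True, 0.02, "down"), ("gC", False, 0.9, "none")]
        )
        dml = _dml_table([("p1", "gA", "TSS200", True, 0.01, 5.0)])
        s = summarize_gene_methylation(dml, 3)
        n, pct = count_dmegs(deg, s, 3)
        assert n == 1
        assert pct == 50

    def test_zero_degs_percentage_missing(self):
        deg = _deg_table([("gA", False, 0.9, "none")])
        s = pd.DataFrame(columns=["promoter_delta", "has_promoter_dml"])
        n, pct = count_dmegs(deg, s, 3)
        assert n == 0 and pct is None


class TestAssociation:
    def test_proportional_table_gives_unit_odds_ratio(self):
        oratio, corrected = odds_ratio_2x2(10, 20, 30, 60)
        assert oratio == 1.0 and not corrected

    def test_or_and_chi2_on_balanced_table(self):
        deg = _deg_table(
            [(f"g{i}", i < 30, 0.01 if i < 30 else 0.9, "up") for i in range(60)]
        )
        dml_rows = [
            (f"p{i}", f"g{i}", "TSS200", True, 0.01, 5.0)
            for i in list(range(20)) + list(range(30, 40))
        ]
        s = summarize_gene_methylation(_dml_table(dml_rows), 3)
        res = deg_dml_association(deg, {3: s}, universe_size=60)
        assert (res.a, res.b, res.c, res.d) == (20, 10, 10, 20)
        assert res.odds_ratio == pytest.approx(4.0)
        # brute-force Pearson chi-squared from expected counts
        assert res.chi2 == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / (30**4))
        assert res.chi2 == pytest.approx(6.6667, abs=1e-3)

    def test_zero_cell_haldane_correction(self):
        oratio, corrected = odds_ratio_2x2(0, 10, 5, 20)
        assert corrected
        assert oratio == pytest.approx((0.5 * 20.5) / (10.5 * 5.5))
        assert 0 < oratio < np.inf

    def test_marginals_conserved(self):
        deg = _deg_table(
            [(f"g{i}", i % 3 == 0, 0.01, "up") for i in range(30)]
        )
        s = summarize_gene_methylation(
            _dml_table([(f"p{i}", f"g{i}", "TSS1500", True, 0.01, 2.0) for i in range(7)]),
            3,
        )
        res = deg_dml_association(deg, {3: s}, universe_size=100)
        assert res.a + res.b == int(deg["is_deg"].sum())
        assert sum(res.counts) == 100

    def test_universe_too_small_rejected(self):
        deg = _deg_table([(f"g{i}", True, 0.01, "up") for i in range(10)])
        s = pd.DataFrame(columns=["promoter_delta", "has_promoter_dml"])
        with pytest.raises(ValueError):
            deg_dml_association(deg, {3: s}, universe_size=5)

    def test_or_grows_with_promoter_targeting(self):
        # planted DMLs aimed at DEG promoters with increasing probability
        from triomic import generate_annotation

        expr = generate_expression(seed=21)
        deg_res = DifferentialExpressionModel.from_study(expr).fit()
        deg_genes = list(expr.truth_any().index[expr.truth_any()])
        annot = generate_annotation(n_genes=500, seed=23)
        annot.table["gene_id"] = list(expr.rpkm.index)  # shared gene universe
        ors = []
        for q in (0.0, 0.8):
            meth = generate_methylation(
                n_probes=800, frac_dml=0.15, seed=22, annotation=annot,
                favor_genes=deg_genes, favor_prob=q,
            )
            dml_res = MethylationModel.from_study(meth).fit()
            summaries = {
                d: summarize_gene_methylation(dml_res.table, d)
                for d in (3, 6, 9)
            }
            res = deg_dml_association(
                deg_res.table, summaries, universe_size=len(deg_res.table)
            )
            ors.append(res.odds_ratio)
        assert ors[1] > 1.0
        assert ors[1] > ors[0]


class TestConcordance:
    def test_all_hypo_up_fully_concordant_under_inverse_rule(self):
        deg = _deg_table([("gA", True, 0.01, "up"), ("gB", True, 0.01, "up")])
        dml = _dml_table(
            [
                ("p1", "gA", "TSS200", True, 0.01, -5.0),
                ("p2", "gB", "TSS1500", True, 0.01, -8.0),
            ]
        )
        s = summarize_gene_methylation(dml, 3)
        res = concordance(deg, s, 3, scope="promoter", convention="promoter_inverse")
        assert res.fraction == 1.0
        assert res.n_eligible == 2

    def test_single_hyper_up_is_discordant_under_inverse_rule(self):
        deg = _deg_table([("gA", True, 0.01, "up")])
        s = summarize_gene_methylation(
            _dml_table([("p1", "gA", "TSS200", True, 0.01, 5.0)]), 3
        )
        res = concordance(deg, s, 3, convention="promoter_inverse")
        assert res.fraction == 0.0
        same = concordance(deg, s, 3, convention="same_sign")
        assert same.fraction == 1.0

    def test_independent_signs_give_half_concordance(self):
        rng = np.random.default_rng(17)
        n = 2000
        deg = _deg_table(
            [(f"g{i}", True, 0.01, rng.choice(["up", "down"])) for i in range(n)]
        )
        dml = _dml_table(
            [
                (f"p{i}", f"g{i}", "TSS200", True, 0.01, float(rng.choice([-5.0, 5.0])))
                for i in range(n)
            ]
        )
        s = summarize_gene_methylation(dml, 3)
        res = concordance(deg, s, 3)
        se = np.sqrt(0.25 / n)
        assert abs(res.fraction - 0.5) < 4 * se

    def test_no_eligible_genes_is_missing(self):
        deg = _deg_table([("gA", True, 0.01, "up")])
        s = pd.DataFrame(
            {"promoter_delta": [np.nan], "has_promoter_dml": [False]},
            index=pd.Index(["gA"], name="gene_id"),
        )
        res = concordance(deg, s, 3)
        assert res.fraction is None and res.n_eligible == 0
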