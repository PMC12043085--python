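"""Germline triage: hard filters, overrepresentation screen, hcD rules,
burden statistics — each against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ieilgl import germline, stats
from ieilgl.config import RunConfig
from ieilgl.germline import TriageError
from tests.conftest import make_germline_row
from tests.test_stats import binomial_tail_oracle, bh_oracle


def frame(rows):
    return pd.DataFrame(rows)


class TestFilterCandidates:
    @pytest.mark.parametrize("override,passes", [
        ({}, True),
        ({"depth": 9}, False),                      # below minimum depth
        ({"alt_reads": 3}, False),                  # too few alternate reads
        ({"vaf": 0.35}, False),                     # sub-germline VAF
        ({"population_af": 0.02}, False),           # not rare
        ({"population_af": 0.01}, False),           # boundary: must be < 1%
        ({"population_af": 0.0099}, True),
        ({"consequence": "synonymous"}, False),
        ({"consequence": "other"}, False),
        ({"consequence": "splice_site"}, True),
        ({"consequence": "nonsense"}, True),
        ({"in_repetitive_region": True}, False),
        ({"matches_somatic_call": True}, False),    # duplicate of somatic call
        ({"acmg": "B"}, False),
        ({"acmg": "LB"}, False),
        ({"acmg": "P"}, True),
        ({"depth": 10, "alt_reads": 4, "vaf": 0.40}, True),  # all boundaries pass
    ])
    def test_each_clause(self, override, passes):
        df = germline.filter_candidates(frame([make_germline_row(**override)]))
        assert bool(df["passed_filters"].iloc[0]) is passes

    def test_pure_flagging_preserves_rows(self):
        rows = [make_germline_row(), make_germline_row(depth=5, patient_id="P002")]
        df = germline.filter_candidates(frame(rows))
        assert len(df) == 2


class TestOverrepresentationScreen:
    def test_pvalue_matches_summation_oracle(self, cfg):
        # one VUS seen het in 3 of 92 patients at MAF 0.001
        rows = [make_germline_row(patient_id=f"P{i:03d}", population_af=0.001)
                for i in range(3)]
        out = germline.overrepresentation_screen(
            germline.filter_candidates(frame(rows)), cohort_n=92, cfg=cfg)
        expected = binomial_tail_oracle(3, 184, 0.001)
        assert out["overrep_p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_plp_selected_regardless_of_q(self, cfg):
        rows = [make_germline_row(acmg="LP", population_af=0.009)]
        out = germline.overrepresentation_screen(
            germline.filter_candidates(frame(rows)), cohort_n=92, cfg=cfg)
        # a single het carrier at MAF 0.9% is nowhere near overrepresented
        assert out["overrep_p"].iloc[0] > 0.5
        assert bool(out["selected"].iloc[0])

    def test_vus_selection_follows_bh_oracle(self, cfg):
        # three VUS: one strongly enriched, two at expectation
        rows = (
            [make_germline_row(patient_id=f"P{i:03d}", gene="BACH2",
                               hgvs="c.31A>T", population_af=1e-4)
             for i in range(5)]
            + [make_germline_row(patient_id="P010", gene="AIRE",
                                 hgvs="c.100A>G", population_af=0.005)]
            + [make_germline_row(patient_id="P011", gene="PRF1",
                                 hgvs="c.272C>T", population_af=0.008)]
        )
        out = germline.overrepresentation_screen(
            germline.filter_candidates(frame(rows)), cohort_n=92, cfg=cfg)
        per_variant = out.drop_duplicates(["gene", "hgvs"]).set_index("gene")
        pvals = [binomial_tail_oracle(5, 184, 1e-4),
                 binomial_tail_oracle(1, 184, 0.005),
                 binomial_tail_oracle(1, 184, 0.008)]
        expected_reject = dict(zip(["BACH2", "AIRE", "PRF1"], bh_oracle(pvals, 0.05)))
        for gene, rej in expected_reject.items():
            assert bool(per_variant.loc[gene, "selected"]) is rej

    def test_hom_counts_two_alleles(self, cfg):
        rows = [make_germline_row(zygosity="hom", population_af=0.001)]
        out = germline.overrepresentation_screen(
            germline.filter_candidates(frame(rows)), cohort_n=92, cfg=cfg)
        assert out["overrep_p"].iloc[0] == pytest.approx(
            binomial_tail_oracle(2, 184, 0.001), abs=1e-12)

    def test_zero_af_floored_not_degenerate(self, cfg):
        rows = [make_germline_row(population_af=0.0)]
        out = germline.overrepresentation_screen(
            germline.filter_candidates(frame(rows)), cohort_n=92, cfg=cfg)
        p = out["overrep_p"].iloc[0]
        assert 0.0 < p < 1.0
        assert p == pytest.approx(
            binomial_tail_oracle(1, 184, 1.0 / (2 * cfg.reference_cohort_size)),
            abs=1e-12)

    def test_duplicate_patient_variant_rejected(self, cfg):
        rows = [make_germline_row(), make_germline_row()]
        with pytest.raises(TriageError, match="duplicate"):
            germline.overrepresentation_screen(
                germline.filter_candidates(frame(rows)), cohort_n=92, cfg=cfg)

    def test_selection_monotone_in_alpha(self, cfg, rng):
        rows = []
        for v in range(12):
            af = float(rng.uniform(1e-4, 9e-3))
            for i in range(int(rng.integers(1, 5))):
                rows.append(make_germline_row(
                    patient_id=f"P{i:03d}", gene=f"G{v}", hgvs=f"c.{v}A>G",
                    population_af=af))
        flagged = germline.filter_candidates(frame(rows))
        selected_prev = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            cfg_a = RunConfig(fdr_alpha=alpha)
            out = germline.overrepresentation_screen(flagged, 92, cfg_a)
            sel = set(map(tuple, out.loc[out["selected"], ["gene", "hgvs"]].values))
            if selected_prev is not None:
                assert sel <= selected_prev
            selected_prev = sel


def hcd_oracle(variants, inheritance_by_gene):
    """Literal restatement of the hcD rules, independent of the classifier."""
    tags = set()
    if any(v["acmg"] in ("P", "LP") for v in variants):
        tags.add("a")
    for v in variants:
        if (v["acmg"] == "VUS" and v["zygosity"] == "het"
                and inheritance_by_gene[v["gene"]] in ("AD", "AD_AR")):
            tags.add("b")
    genes = {v["gene"] for v in variants}
    for g in genes:
        if inheritance_by_gene[g] not in ("AR", "AD_AR", "XL"):
            continue
        mine = [v for v in variants if v["gene"] == g]
        if any(v["zygosity"] == "hom" for v in mine):
            tags.add("c")
        elif len({v["hgvs"] for v in mine if v["zygosity"] == "het"}) >= 2:
            tags.add("c")
    return bool(tags), tags


class TestClassifyHcd:
    def panel_for(self, inheritance):
        return pd.DataFrame({
            "gene": ["GENE1"], "iuis_category": ["other"],
            "inheritance": [inheritance], "onset": ["adult"],
        })

    def test_single_variant_decision_table(self):
        """Every (acmg, zygosity, inheritance) combination matches the oracle."""
        for acmg, zyg, inh in itertools.product(
                ["P", "LP", "VUS"], ["het", "hom"], ["AD", "AR", "XL", "AD_AR"]):
            variants = frame([make_germline_row(gene="GENE1", acmg=acmg, zygosity=zyg)])
            got, tags = germline.classify_hcd(variants, self.panel_for(inh))
            want, want_tags = hcd_oracle(
                [{"gene": "GENE1", "acmg": acmg, "zygosity": zyg, "hgvs": "c.100A>G"}],
                {"GENE1": inh})
            assert (got, set(tags)) == (want, want_tags), (acmg, zyg, inh)

    def test_two_variant_decision_table(self):
        """Pairs of variants in one gene (incl. presumed compound het) match."""
        combos = itertools.product(["P", "VUS"], ["het", "hom"], repeat=2)
        for (a1, z1), (a2, z2) in ((c[:2], c[2:]) for c in combos):
            for inh in ["AD", "AR", "AD_AR", "XL"]:
                rows = [
                    make_germline_row(gene="GENE1", acmg=a1, zygosity=z1, hgvs="c.1A>G"),
                    make_germline_row(gene="GENE1", acmg=a2, zygosity=z2, hgvs="c.2A>G"),
                ]
                got, tags = germline.classify_hcd(frame(rows), self.panel_for(inh))
                want, want_tags = hcd_oracle(
                    [{"gene": "GENE1", "acmg": a, "zygosity": z, "hgvs": h}
                     for a, z, h in [(a1, z1, "c.1A>G"), (a2, z2, "c.2A>G")]],
                    {"GENE1": inh})
                assert (got, set(tags)) == (want, want_tags)

    def test_het_plp_is_hcd(self, small_panel):
        variants = frame([make_germline_row(gene="AIRE", acmg="LP")])
        is_hcd, tags = germline.classify_hcd(variants, small_panel)
        assert is_hcd and tags == ["a"]

    def test_het_vus_in_recessive_gene_is_not_hcd(self, small_panel):
        variants = frame([make_germline_row(gene="PRF1", acmg="VUS")])
        is_hcd, tags = germline.classify_hcd(variants, small_panel)
        assert not is_hcd

    def test_compound_het_vus_in_recessive_gene(self, small_panel):
        rows = [make_germline_row(gene="PRF1", acmg="VUS", hgvs="c.1A>G"),
                make_germline_row(gene="PRF1", acmg="VUS", hgvs="c.2A>G")]
        is_hcd, tags = germline.classify_hcd(frame(rows), small_panel)
        assert is_hcd and tags == ["c"]

    def test_unknown_gene_raises(self, small_panel):
        variants = frame([make_germline_row(gene="NOTAGENE")])
        with pytest.raises(TriageError, match="NOTAGENE"):
            germline.classify_hcd(variants, small_panel)


class TestBurdenStatistics:
    def make_triage(self, carriers, cohort_n, counts=None, hcd=0):
        pp = pd.DataFrame({
            "patient_id": [f"P{i:03d}" for i in range(cohort_n)],
            "selected_variant_count": (
                (counts or [1] * carriers) + [0] * (cohort_n - carriers)),
            "is_carrier": [True] * carriers + [False] * (cohort_n - carriers),
            "is_hcd_carrier": [True] * hcd + [False] * (cohort_n - hcd),
            "hcd_rules": "",
        })
        return germline.TriageResult(variants=pd.DataFrame(), per_patient=pp,
                                     cohort_n=cohort_n)

    def test_cohort_level_tallies(self):
        counts = [1] * 27 + [2] * 5 + [3] * 2  # median 1, range 1-3
        tri = self.make_triage(34, 92, counts=counts, hcd=15)
        s = germline.burden_statistics(tri, control_carriers=167, control_n=63026)
        assert s["combined_burden_pct"] == 37
        assert s["hcd_rate_pct"] == 16
        assert s["median_variants_in_carriers"] == 1
        assert (s["min_variants_in_carriers"], s["max_variants_in_carriers"]) == (1, 3)
        assert s["chi2_p"] < 0.001
        assert s["control_burden"] == pytest.approx(167 / 63026)

    def test_zero_carriers(self):
        tri = self.make_triage(0, 10)
        s = germline.burden_statistics(tri, control_carriers=0, control_n=100)
        assert s["combined_burden"] == 0.0
        assert s["chi2_p"] == 1.0

    def test_expected_probability_sums_selected_afs(self, cfg, small_panel):
        rows = [make_germline_row(gene="AIRE", acmg="P", population_af=0.002),
                make_germline_row(gene="BACH2", hgvs="c.31A>T", acmg="LP",
                                  population_af=0.003, patient_id="P002")]
        tri = germline.run_triage(frame(rows), small_panel, cohort_n=92, cfg=cfg)
        assert tri.expected_probability == pytest.approx(0.005)
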