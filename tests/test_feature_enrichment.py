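"""Enrichment layers: chi-squared tables, enhancer duplications, cytobands,
copy categories, essentiality crossing."""

import numpy as np
import pandas as pd
import pytest

from svimpact.breakpoint_matrix import GeneModel
from svimpact.feature_enrichment import (EnrichmentResult,
                                         chisq_from_table,
                                         classify_enhancer_duplication,
                                         cohort_cytoband_summary,
                                         copy_category,
                                         copy_category_crosstab,
                                         cross_essentiality,
                                         cytoband_enrichment,
                                         enrichment_chisq,
                                         find_spanning_events)
from svimpact.sv_io import SVRecord

from conftest import random_sv_records


class TestChiSquared:
    def test_balanced_table_is_null(self):
        res = chisq_from_table([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association_matches_pearson_formula(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 40 * 400^2 / 160000 = 40
        res = chisq_from_table([[20, 0], [0, 20]])
        assert res.chi2 == pytest.approx(40.0)
        assert res.enriched

    def test_transposition_invariance(self, rng):
        t = rng.integers(1, 50, size=(2, 2))
        a, b = chisq_from_table(t), chisq_from_table(t.T)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_margin_flagged(self):
        res = chisq_from_table([[0, 0], [5, 7]])
        assert res.p is None and res.note == "degenerate margin"

    def test_low_expected_cell_warns(self):
        with pytest.warns(UserWarning, match="expected cell"):
            enrichment_chisq([True] * 3 + [False] * 60,
                             [True, False, True] + [False] * 60)


def gene_at(start=1_000_000, end=1_020_000, strand="+"):
    return GeneModel("g", "chr1", start, end, strand)


def dup(pos_a, pos_b, cls="DUP"):
    return SVRecord("s", "P1", "chr1", pos_a, "chr1", pos_b, cls, "germline")


class TestEnhancerDuplication:
    def test_upstream_dup_containing_enhancer(self):
        gene = gene_at()
        sv = dup(985_000, 995_000)  # both breakpoints 10 kb upstream-ish
        enh = [("chr1", 988_000, 989_000)]
        assert classify_enhancer_duplication(sv, gene, enh)

    def test_same_geometry_deletion_is_not(self):
        gene = gene_at()
        sv = dup(985_000, 995_000, cls="DEL")
        enh = [("chr1", 988_000, 989_000)]
        assert not classify_enhancer_duplication(sv, gene, enh)

    def test_breakpoint_inside_gene_disqualifies(self):
        gene = gene_at()
        sv = dup(985_000, 1_005_000)
        enh = [("chr1", 988_000, 989_000)]
        assert not classify_enhancer_duplication(sv, gene, enh)

    def test_spanning_dup_disqualifies(self):
        gene = gene_at()
        sv = dup(990_000, 1_030_000)
        enh = [("chr1", 991_000, 992_000)]
        assert not classify_enhancer_duplication(sv, gene, enh)

    def test_partial_enhancer_overlap_not_enough_by_default(self):
        gene = gene_at()
        sv = dup(985_000, 995_000)
        enh = [("chr1", 994_000, 996_000)]  # sticks out of the SV
        assert not classify_enhancer_duplication(sv, gene, enh)
        assert classify_enhancer_duplication(sv, gene, enh,
                                             whole_enhancer=False)

    def test_monotone_in_enhancer_set(self, rng):
        gene = gene_at()
        svs = [dup(int(a), int(a) + int(s))
               for a, s in zip(rng.integers(880_000, 1_100_000, 50),
                               rng.integers(1_000, 40_000, 50))]
        enh_small = [("chr1", int(p), int(p) + 500)
                     for p in rng.integers(900_000, 1_100_000, 5)]
        enh_big = enh_small + [("chr1", int(p), int(p) + 500)
                               for p in rng.integers(900_000, 1_100_000, 20)]
        for sv in svs:
            small = classify_enhancer_duplication(sv, gene, enh_small)
            big = classify_enhancer_duplication(sv, gene, enh_big)
            assert big or not small

    def test_matches_literal_reimplementation(self, rng):
        genes = [gene_at(int(s), int(s) + 20_000,
                         "+" if rng.random() < .5 else "-")
                 for s in rng.integers(500_000, 1_500_000, 10)]
        svs = random_sv_records(rng, 100, chroms=("chr1",), tra_fraction=0,
                                max_pos=2_000_000)
        enh = [("chr1", int(p), int(p) + 800)
               for p in rng.integers(0, 2_000_000, 50)]
        flank = 100_000
        for sv in svs:
            for gene in genes:
                # literal restatement of the five conditions
                in_flank = all(
                    (gene.start - flank <= pos < gene.start)
                    or (gene.end <= pos < gene.end + flank)
                    for pos in (sv.pos_a, sv.pos_b))
                spans = sv.pos_a <= gene.start and sv.pos_b >= gene.end
                inside = any(gene.start <= pos < gene.end
                             for pos in (sv.pos_a, sv.pos_b))
                contains_enh = any(sv.pos_a <= s and e <= sv.pos_b
                                   for _, s, e in enh)
                expected = (sv.sv_class == "DUP" and in_flank
                            and not spans and not inside and contains_enh)
                got = classify_enhancer_duplication(sv, gene, enh)
                assert got == expected


class TestCytobands:
    def bands(self, n=10, width=1_000_000):
        return [("chr1", i * width, (i + 1) * width, f"b{i}")
                for i in range(n)]

    def test_concentrated_breakpoints_highly_significant(self):
        svs = [SVRecord(f"s{i}", "P1", "chr1", 2_000_000 + i * 100,
                        "chr1", 2_500_000 + i * 100, "DEL", "germline")
               for i in range(50)]  # 100 breakpoints in band b2
        res = cytoband_enrichment(svs, self.bands())
        assert res["b2"].p < 1e-10 and res["b2"].enriched
        # chi2 for 100/0 observed vs 10/90 expected = 810 + 90
        assert res["b2"].chi2 == pytest.approx(900.0)

    def test_uniform_breakpoints_not_significant(self, rng):
        svs = []
        for i in range(200):
            pa = int(rng.integers(0, 9_999_000))
            svs.append(SVRecord(f"s{i}", "P1", "chr1", pa, "chr1",
                                pa + 500, "DEL", "germline"))
        res = cytoband_enrichment(svs, self.bands())
        assert all(r.p is None or r.p > 1e-4 for r in res.values())

    def test_zero_sv_patient_has_no_tested_bands(self):
        assert cytoband_enrichment([], self.bands()) == {}

    def test_min_patients_gate(self):
        per_patient = {"P1": cytoband_enrichment(
            [SVRecord(f"s{i}", "P1", "chr1", 100 + i, "chr1", 200 + i,
                      "DEL", "germline") for i in range(60)], self.bands())}
        assert cohort_cytoband_summary(per_patient, min_patients=2) == []
        assert cohort_cytoband_summary(per_patient, min_patients=1) == ["b0"]

    def test_patient_order_invariance(self, rng):
        patients = {}
        for p in ("P1", "P2", "P3"):
            patients[p] = cytoband_enrichment(
                random_sv_records(rng, 50, chroms=("chr1",), tra_fraction=0,
                                  max_pos=9_000_000), self.bands())
        forward = cohort_cytoband_summary(patients, p_threshold=0.5,
                                          min_patients=1)
        backward = cohort_cytoband_summary(
            dict(reversed(list(patients.items()))), p_threshold=0.5,
            min_patients=1)
        assert forward == backward


class TestCopyCategories:
    @pytest.mark.parametrize("copies,expected", [
        (6, "amplification"), (5.01, "amplification"),
        (5, "copy_gain"), (3, "copy_gain"), (4.2, "copy_gain"),
        (2, "neutral"), (1.5, "neutral"), (2.9, "neutral"),
        (1, "copy_loss"), (0, "copy_loss"), (0.5, "copy_loss"),
    ])
    def test_exact_bin_boundaries(self, copies, expected):
        assert copy_category(copies) == expected

    def test_crosstab_with_planted_relationship(self):
        genes = [GeneModel(f"g{i}", "chr1", (i + 1) * 100_000,
                           (i + 1) * 100_000 + 10_000, "+")
                 for i in range(10)]
        svs, rows = [], {}
        for i, g in enumerate(genes):
            cls = "DUP" if i < 5 else "DEL"
            svs.append(SVRecord(f"s{i}", f"P{i}", "chr1", g.start - 10,
                                "chr1", g.end + 10, cls, "somatic"))
            rows[(g.gene_id, f"P{i}")] = 4.0 if cls == "DUP" else 0.5
        events = find_spanning_events(svs, genes)
        assert len(events) == 10
        copy = pd.DataFrame(2.0, index=[g.gene_id for g in genes],
                            columns=[f"P{i}" for i in range(10)])
        for (gene, sample), v in rows.items():
            copy.loc[gene, sample] = v
        ploidy = pd.Series(2.0, index=copy.columns)
        xtab = copy_category_crosstab(events, copy, ploidy)
        assert xtab.table.loc["DUP", "copy_gain"] == 5
        assert xtab.table.loc["DEL", "copy_loss"] == 5
        assert xtab.dup_gain.p < 0.01 and xtab.dup_gain.enriched
        assert xtab.del_loss.p < 0.01 and xtab.del_loss.enriched

    def test_flat_copy_profile_shows_no_enrichment(self):
        events = [("g0", "P0", "DUP"), ("g0", "P1", "DEL"),
                  ("g1", "P0", "DUP"), ("g1", "P1", "DEL")]
        copy = pd.DataFrame(2.0, index=["g0", "g1"], columns=["P0", "P1"])
        ploidy = pd.Series(2.0, index=["P0", "P1"])
        xtab = copy_category_crosstab(events, copy, ploidy)
        assert (xtab.table[["amplification", "copy_gain",
                            "copy_loss"]].to_numpy() == 0).all()
        assert xtab.dup_gain.p is None  # degenerate: nothing gained


class TestEssentiality:
    def matrix(self):
        rng = np.random.default_rng(1)
        ess = pd.DataFrame(rng.normal(0, 0.1, size=(3, 100)),
                           index=["never", "sometimes", "often"],
                           columns=[f"cl{i}" for i in range(100)])
        ess.loc["sometimes", ess.columns[:6]] = -1.0   # 6% of lines
        ess.loc["often", ess.columns[:40]] = -2.0      # 40% of lines
        return ess

    def test_fraction_threshold(self):
        ess = self.matrix()
        got = cross_essentiality(["never", "sometimes", "often"], ess)
        assert got == ["often", "sometimes"]

    def test_missing_gene_excluded_with_warning(self):
        ess = self.matrix()
        with pytest.warns(UserWarning, match="absent"):
            got = cross_essentiality(["often", "ghost"], ess)
        assert got == ["often"]

    def test_randomized_matrix_background_rate(self, rng):
        # with iid scores, overlap ~ |genes_up| x background fraction
        genes = [f"g{i}" for i in range(400)]
        ess = pd.DataFrame(rng.normal(-0.5, 0.2, size=(400, 50)),
                           index=genes)
        background = (ess < -0.75).mean(axis=1).gt(0.05).mean()
        got = cross_essentiality(genes, ess)
        assert len(got) / len(genes) == pytest.approx(background, abs=0.01)
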