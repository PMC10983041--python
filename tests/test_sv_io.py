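"""SV table I/O, caller merging, recurrence, catalog overlap, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svimpact.sv_io import (SVRecord, annotate_known, compute_recurrence,
                            merge_callsets, read_sv_table, summarize_svs,
                            write_sv_table)

from conftest import random_sv_records


def make(sv_id, patient, chrom_a, pos_a, chrom_b, pos_b, cls,
         origin="germline"):
    return SVRecord(sv_id, patient, chrom_a, pos_a, chrom_b, pos_b, cls,
                    origin)


class TestSVRecord:
    def test_canonical_breakpoint_order(self):
        r = make("a", "P1", "chr1", 500, "chr1", 100, "DEL")
        assert (r.pos_a, r.pos_b) == (100, 500)
        assert r.span == 400

    def test_class_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="class/geometry"):
            make("a", "P1", "chr1", 1, "chr2", 2, "DEL")
        with pytest.raises(ValueError, match="class/geometry"):
            make("a", "P1", "chr1", 1, "chr1", 2, "TRA")

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make("a", "P1", "chr1", -5, "chr1", 10, "DEL")

    def test_translocation_has_no_span(self):
        r = make("a", "P1", "chr1", 1, "chr2", 2, "TRA")
        assert r.span is None


class TestTableIO:
    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        write_sv_table([], path)
        assert read_sv_table(path, "germline") == []

    def test_unknown_class_token_named_in_error(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        pd.DataFrame({
            "chrom_a": ["chr1"], "start_a": [1], "end_a": [2],
            "chrom_b": ["chr1"], "start_b": [5], "end_b": [6],
            "sv_id": ["x"], "sv_class": ["WEIRD"], "patient_id": ["P1"],
            "origin": ["germline"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="WEIRD"):
            read_sv_table(path, "germline")

    def test_round_trip_identity(self, tmp_path, rng):
        records = random_sv_records(rng, 1000, n_patients=30)
        path = tmp_path / "cohort.bedpe"
        write_sv_table(records, path)
        back = read_sv_table(path, "germline")
        assert back == records


def brute_force_merge(a, b, slop, require_class_match=False):
    """Independent exhaustive re-implementation of the greedy 1:1 merge."""
    pairs = []
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            if (ra.chrom_a, ra.chrom_b) != (rb.chrom_a, rb.chrom_b):
                continue
            if require_class_match and ra.sv_class != rb.sv_class:
                continue
            da, db = abs(ra.pos_a - rb.pos_a), abs(ra.pos_b - rb.pos_b)
            if da <= slop and db <= slop:
                pairs.append((da + db, i, j))
    pairs.sort()
    used_a, used_b, matched = set(), set(), []
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matched.append((i, j))
    return sorted(matched)


class TestMergeCallsets:
    def test_identical_call_emitted_unchanged(self):
        r = make("a", "P1", "chr1", 100, "chr1", 2100, "DEL")
        s = make("b", "P1", "chr1", 100, "chr1", 2100, "DEL")
        merged = merge_callsets([r], [s])
        assert merged.records == [r]
        assert merged.provenance == [("a", "b")]

    @pytest.mark.parametrize("offset,expected", [(200, 1), (201, 0)])
    def test_slop_boundary_inclusive_at_200(self, offset, expected):
        r = make("a", "P1", "chr1", 1000, "chr1", 5000, "DEL")
        s = make("b", "P1", "chr1", 1000 + offset, "chr1", 5000, "DEL")
        assert len(merge_callsets([r], [s], slop_bp=200).records) == expected

    def test_self_merge_emits_everything(self, rng):
        a = random_sv_records(rng, 200)
        for slop in (0, 10, 500):
            assert len(merge_callsets(a, a, slop_bp=slop).records) == len(a)

    def test_merge_size_bounded_and_monotone_in_slop(self, rng):
        a = random_sv_records(rng, 150, max_pos=50_000)
        b = random_sv_records(rng, 120, max_pos=50_000)
        sizes = [len(merge_callsets(a, b, slop_bp=s).records)
                 for s in (0, 50, 500, 5_000)]
        assert all(n <= min(len(a), len(b)) for n in sizes)
        assert sizes == sorted(sizes)

    def test_jittered_replicate_fully_recovered(self, rng):
        truth = random_sv_records(rng, 500, n_patients=1, max_pos=10**7)
        jittered = []
        for i, r in enumerate(truth):
            ja, jb = rng.integers(-50, 51, size=2)
            jittered.append(SVRecord(
                f"j{i}", r.patient_id, r.chrom_a, max(0, r.pos_a + ja),
                r.chrom_b, max(0, r.pos_b + jb), r.sv_class, r.origin))
        merged = merge_callsets(truth, jittered, slop_bp=200)
        assert len(merged.records) == len(truth)
        oracle = brute_force_merge(truth, jittered, 200)
        got = sorted(
            (truth.index(r), [x.sv_id for x in jittered].index(pj))
            for r, (_, pj) in zip(merged.records, merged.provenance))
        assert got == oracle

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(5):
            a = random_sv_records(rng, 80, max_pos=20_000)
            b = random_sv_records(rng, 80, max_pos=20_000)
            merged = merge_callsets(a, b, slop_bp=300)
            ids_b = [x.sv_id for x in b]
            got = sorted((a.index(r), ids_b.index(pj))
                         for r, (_, pj) in zip(merged.records,
                                               merged.provenance))
            assert got == brute_force_merge(a, b, 300)


breakpoint_pairs = st.lists(
    st.tuples(st.integers(0, 5_000), st.integers(0, 5_000)),
    min_size=0, max_size=30)


class TestMergeProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(pairs=breakpoint_pairs, slop=st.integers(0, 300))
    def test_self_merge_idempotent_for_any_slop(self, pairs, slop):
        records = [make(f"sv{i}", "P1", "chr1", min(a, b), "chr1",
                        max(a, b), "DEL") for i, (a, b) in enumerate(pairs)]
        merged = merge_callsets(records, records, slop_bp=slop)
        assert merged.records == records

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(pairs_a=breakpoint_pairs, pairs_b=breakpoint_pairs,
           slops=st.tuples(st.integers(0, 150), st.integers(151, 400)))
    def test_size_bound_and_slop_monotonicity(self, pairs_a, pairs_b, slops):
        a = [make(f"a{i}", "P1", "chr1", min(x, y), "chr1", max(x, y),
                  "DEL") for i, (x, y) in enumerate(pairs_a)]
        b = [make(f"b{i}", "P1", "chr1", min(x, y), "chr1", max(x, y),
                  "DEL") for i, (x, y) in enumerate(pairs_b)]
        tight = len(merge_callsets(a, b, slop_bp=min(slops)).records)
        loose = len(merge_callsets(a, b, slop_bp=max(slops)).records)
        assert tight <= loose <= min(len(a), len(b))


def brute_force_recurrence(records, slop):
    """Quadratic all-pairs oracle for breakpoint recurrence."""
    out = []
    for r in records:
        both = either = False
        for q in records:
            if q.patient_id == r.patient_id:
                continue
            if (q.chrom_a, q.chrom_b) != (r.chrom_a, r.chrom_b):
                continue
            match_a = abs(q.pos_a - r.pos_a) <= slop
            match_b = abs(q.pos_b - r.pos_b) <= slop
            both = both or (match_a and match_b)
            either = either or match_a or match_b
        out.append((both, either))
    return out


class TestRecurrence:
    def test_two_patients_identical_sv(self):
        recs = [make("a", "P1", "chr1", 100, "chr1", 500, "DEL"),
                make("b", "P2", "chr1", 100, "chr1", 500, "DEL")]
        flags = compute_recurrence(recs)
        assert all(f.both_shared and f.either_shared for f in flags)

    def test_single_patient_never_recurrent(self, rng):
        recs = random_sv_records(rng, 50, n_patients=1)
        flags = compute_recurrence(recs)
        assert not any(f.both_shared or f.either_shared for f in flags)

    def test_matches_brute_force(self, rng):
        recs = random_sv_records(rng, 300, max_pos=5_000, n_patients=8)
        flags = compute_recurrence(recs, slop_bp=10)
        oracle = brute_force_recurrence(recs, 10)
        assert [(f.both_shared, f.either_shared) for f in flags] == oracle

    def test_symmetry(self, rng):
        # if r is both_shared thanks to q, q must be both_shared too
        recs = random_sv_records(rng, 120, max_pos=2_000, n_patients=4)
        flags = compute_recurrence(recs, slop_bp=25)
        for i, r in enumerate(recs):
            if not flags[i].both_shared:
                continue
            partners = [
                j for j, q in enumerate(recs)
                if q.patient_id != r.patient_id
                and (q.chrom_a, q.chrom_b) == (r.chrom_a, r.chrom_b)
                and abs(q.pos_a - r.pos_a) <= 25
                and abs(q.pos_b - r.pos_b) <= 25]
            assert partners and all(flags[j].both_shared for j in partners)


class TestAnnotateKnown:
    def test_verbatim_catalog_member(self):
        r = make("a", "P1", "chr1", 100, "chr1", 500, "DEL")
        assert annotate_known([r], [r], slop_bp=0) == [True]

    def test_empty_catalog_is_an_error(self):
        r = make("a", "P1", "chr1", 100, "chr1", 500, "DEL")
        with pytest.raises(ValueError, match="catalog"):
            annotate_known([r], [])

    def test_planted_sixty_percent_subset(self, rng):
        cohort = random_sv_records(rng, 200, max_pos=10**7)
        catalog = cohort[:120]
        flags = annotate_known(cohort, catalog, slop_bp=0)
        # duplicated coordinates could only raise the fraction above 60%
        assert sum(flags[:120]) == 120
        assert sum(flags) / len(flags) == pytest.approx(0.6, abs=0.02)


class TestSummarize:
    def test_single_deletion(self):
        r = make("a", "P1", "chr1", 1_000, "chr1", 3_000, "DEL")
        s = summarize_svs([r])
        assert s.median_intra_size == 2_000
        assert s.class_fractions == {"DEL": 1.0}
        assert s.per_patient_counts == {"P1": 1}

    def test_all_translocations_have_no_median_size(self):
        recs = [make(f"t{i}", f"P{i}", "chr1", 10, "chr2", 20, "TRA")
                for i in range(3)]
        assert summarize_svs(recs).median_intra_size is None

    def test_recurrence_fraction_ordering(self, rng):
        recs = random_sv_records(rng, 200, max_pos=3_000, n_patients=6)
        s = summarize_svs(recs)
        assert s.recurrence_fraction_both <= s.recurrence_fraction_either
        assert abs(sum(s.class_fractions.values()) - 1) < 1e-12
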