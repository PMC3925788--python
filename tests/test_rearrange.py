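"""Split-alignment parsing, chaining, footprints, and gene proximity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomosaic import (
    AlignmentRecord,
    GeneAnnotation,
    SimulationConfig,
    annotate_breakpoints,
    apply_recombination,
    breakpoint_footprint,
    chain_and_classify,
    classify_all,
    compare_presence,
    generate_master_circle,
    read_tabular_alignments,
    seed_extend_align,
)
from mitomosaic.io import published_alignment_path


def rec(qid="q", qs=1, qe=100, ss=1, se=100, ident=100.0, length=None):
    return AlignmentRecord(query_id=qid, pct_identity=ident,
                           align_length=length or (qe - qs + 1),
                           q_start=qs, q_end=qe, s_start=ss, s_end=se)


class TestReadTabularAlignments:
    def test_plus_and_minus_strand_inference(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "AJJZ010142287.1\t99.18\t612\t1\t612\t338444\t339054\t0\n"
            "AJJZ011005166.1\t98.79\t1077\t241\t1317\t21535\t20459\t0\n"
        )
        records = read_tabular_alignments(p)
        assert records[0].strand == "+"
        assert (records[0].q_start, records[0].q_end) == (1, 612)
        assert records[1].strand == "-"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert read_tabular_alignments(p) == []

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q\t99\tnot_an_int\t1\t10\t1\t10\t0\n")
        with pytest.raises(ValueError, match="line 1"):
            read_tabular_alignments(p)

    def test_bundled_table_has_eleven_queries(self):
        records = read_tabular_alignments(published_alignment_path())
        assert len(records) == 28
        assert len({r.query_id for r in records}) == 11


class TestBreakpointFootprint:
    @pytest.mark.parametrize("iv1,iv2,expect", [
        ((1, 612), (512, 1096), (101, 0)),     # the 101 bp repeat footprint
        ((1, 7965), (7733, 9596), (233, 0)),   # overlap arithmetic
        ((1, 100), (200, 300), (0, 99)),       # clean insertion
        ((1, 100), (101, 200), (0, 0)),        # abutting segments
    ])
    def test_footprint_and_insertion(self, iv1, iv2, expect):
        s1 = rec(qs=iv1[0], qe=iv1[1])
        s2 = rec(qs=iv2[0], qe=iv2[1], ss=5000, se=5000 + iv2[1] - iv2[0])
        assert breakpoint_footprint(s1, s2) == expect

    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_nonnegative_and_exclusive(self, a, b, c, d):
        qs1, qe1 = min(a, b), max(a, b)
        qs2, qe2 = min(c, d), max(c, d)
        s1, s2 = rec(qs=qs1, qe=qe1), rec(qs=qs2, qe=qe2)
        fp, ins = breakpoint_footprint(s1, s2)
        assert (fp, ins) == breakpoint_footprint(s2, s1)
        assert fp >= 0 and ins >= 0
        assert fp * ins == 0


class TestChainAndClassify:
    def test_single_segment_is_colinear(self):
        call = chain_and_classify([rec()])
        assert call.classification == "colinear"
        assert call.breakpoints == []

    def test_no_records_is_unaligned(self):
        assert chain_and_classify([]).classification == "unaligned"

    def test_distant_subject_gap_is_rearranged(self):
        call = chain_and_classify([
            rec(qs=1, qe=612, ss=338444, se=339054),
            rec(qs=512, qe=1096, ss=854280, se=854864),
        ])
        assert call.classification == "rearranged"
        assert call.breakpoints[0].footprint_length == 101

    def test_colinear_chain_with_small_gap(self):
        call = chain_and_classify([
            rec(qs=1, qe=100, ss=1000, se=1099),
            rec(qs=101, qe=200, ss=1150, se=1249),
        ])
        assert call.classification == "colinear"

    def test_strand_switch_is_rearranged(self):
        call = chain_and_classify([
            rec(qs=1, qe=100, ss=1000, se=1099),
            rec(qs=120, qe=220, ss=2200, se=2100),
        ])
        assert call.classification == "rearranged"

    def test_published_contig_with_four_segments(self):
        records = read_tabular_alignments(published_alignment_path())
        groups = classify_all(records)
        call = groups["AJJZ010174367.1"]
        assert len(call.segments) == 4
        assert call.classification == "rearranged"

    def test_published_table_yields_eleven_rearranged(self):
        records = read_tabular_alignments(published_alignment_path())
        groups = classify_all(records)
        n = sum(c.classification == "rearranged" for c in groups.values())
        assert n == 11

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(ValueError):
            chain_and_classify([rec(qid="a"), rec(qid="b")])


class TestSeedExtendAlign:
    def test_exact_substring_single_segment(self, small_sim):
        _, genome, _ = small_sim
        q = genome.sequence[1000:1400]
        (r,) = [x for x in seed_extend_align(q, genome, query_id="q")
                if x.align_length >= 400]
        assert (r.q_start, r.q_end) == (1, 400)
        assert (r.s_start, r.s_end) == (1001, 1400)
        assert r.strand == "+"

    def test_reverse_complement_single_minus_segment(self, small_sim):
        from mitomosaic.core import revcomp

        _, genome, _ = small_sim
        q = revcomp(genome.sequence[2000:2300])
        (r,) = [x for x in seed_extend_align(q, genome, query_id="q")
                if x.align_length >= 300]
        assert r.strand == "-"
        assert (r.s_low, r.s_high) == (2001, 2300)

    def test_two_distant_substrings_give_two_segments(self, small_sim):
        _, genome, _ = small_sim
        q = genome.sequence[100:400] + genome.sequence[3000:3300]
        segs = [x for x in seed_extend_align(q, genome, query_id="q")
                if x.align_length >= 200]
        assert len(segs) == 2
        assert (segs[0].s_start, segs[0].s_end) == (101, 400)
        assert (segs[1].s_start, segs[1].s_end) == (3001, 3300)

    def test_colinear_on_reference_derived_query(self, small_sim):
        """A query cut straight out of the reference is never rearranged."""
        _, genome, _ = small_sim
        for lo in (0, 1500, 4000):
            q = genome.sequence[lo : lo + 800]
            call = chain_and_classify(seed_extend_align(q, genome, query_id="q"))
            assert call.classification == "colinear"


class TestRecombinantRecovery:
    def test_breakpoints_match_planted_junctions(self):
        """Aligning a recombinant against its source flags both junctions
        at the planted positions with footprint = repeat length."""
        cfg = SimulationConfig(genome_length=9000, repeat_spec=((150, "inverted", 0),),
                               n_genes=2, gene_length_range=(300, 450), rng_seed=31)
        genome, truth = generate_master_circle(cfg)
        rep = truth.planted_repeats[0]
        res = apply_recombination(genome, rep, truth)
        recombinant = res.genomes[0]
        call = chain_and_classify(
            seed_extend_align(recombinant.sequence, genome, query_id="rec"))
        assert call.classification == "rearranged"
        found = {tuple(sorted(bp.subject_positions)) for bp in call.breakpoints}
        for planted, footprint in res.truth.planted_junctions:
            key = tuple(sorted(planted))
            assert any(abs(key[0] - f[0]) <= 50 and abs(key[1] - f[1]) <= 50
                       for f in found)
        for bp in call.breakpoints:
            assert bp.footprint_length == rep.length


class TestAnnotateBreakpoints:
    @staticmethod
    def call_with_breakpoint(ss1, ss2):
        segs = [rec(qs=1, qe=100, ss=ss1 - 99, se=ss1),
                rec(qs=120, qe=220, ss=ss2, se=ss2 + 100)]
        return chain_and_classify(segs)

    def test_minus_strand_gene_distances(self):
        """Junctions at 158290 and 156744 flanking a minus-strand gene at
        156716-158245: 45 bp before the start codon, 28 bp before the end."""
        gene = GeneAnnotation(gene_id="atp1", start=156716, end=158245, strand="-")
        call_start = self.call_with_breakpoint(158290, 500000)
        annotated = annotate_breakpoints(call_start, [gene], window=1000)
        assert annotated.breakpoints[0].nearest_gene[0] == "atp1"
        assert annotated.breakpoints[0].nearest_gene[1] == 45  # before start codon
        call_end = self.call_with_breakpoint(156744, 500000)
        annotated = annotate_breakpoints(call_end, [gene], window=1000)
        assert annotated.breakpoints[0].nearest_gene[2] == 28  # before gene end

    def test_plus_strand_mirror(self):
        """Reflecting the coordinates swaps the roles but keeps distances."""
        n = 1_000_000
        gene = GeneAnnotation(gene_id="atp1r", start=n - 158245 + 1,
                              end=n - 156716 + 1, strand="+")
        p = n - 158290 + 1
        call = self.call_with_breakpoint(p, 500000)
        annotated = annotate_breakpoints(call, [gene], window=1000)
        assert annotated.breakpoints[0].nearest_gene[1] == 45

    def test_far_gene_left_unannotated(self):
        gene = GeneAnnotation(gene_id="g", start=100, end=400, strand="+")
        call = self.call_with_breakpoint(6000, 9000)
        annotated = annotate_breakpoints(call, [gene], window=1000)
        assert annotated.breakpoints[0].nearest_gene is None


class TestComparePresence:
    @staticmethod
    def call_at(ss1, ss2, qid="q"):
        segs = [rec(qid=qid, qs=1, qe=100, ss=ss1 - 99, se=ss1),
                rec(qid=qid, qs=120, qe=220, ss=ss2, se=ss2 + 100)]
        return chain_and_classify(segs)

    def test_shared_breakpoint_not_unique(self):
        calls = {f"v{i}": [self.call_at(5000 + i, 90000 - i)] for i in range(6)}
        matrix = compare_presence(calls)
        assert len(matrix) == 1
        assert matrix.iloc[0]["unique_to"] == ""

    def test_single_sample_breakpoint_flagged(self):
        calls = {f"v{i}": [self.call_at(5000, 90000)] for i in range(5)}
        calls["v5"] = [self.call_at(5000, 90000), self.call_at(40000, 300000)]
        matrix = compare_presence(calls)
        uniq = matrix[matrix["unique_to"] != ""]
        assert len(uniq) == 1
        assert uniq.iloc[0]["unique_to"] == "v5"
        assert uniq.iloc[0]["subject_pos_1"] == 40000

    def test_planted_single_sample_rearrangement(self):
        """One of six synthetic samples carries a recombination; exactly its
        breakpoints are flagged unique."""
        cfg = SimulationConfig(genome_length=9000, repeat_spec=((120, "inverted", 0),),
                               n_genes=2, gene_length_range=(300, 450), rng_seed=13)
        genome, truth = generate_master_circle(cfg)
        rep = truth.planted_repeats[0]
        recombinant = apply_recombination(genome, rep, truth).genomes[0]
        calls = {}
        for i in range(5):
            q = genome.sequence[200:8200]
            calls[f"v{i}"] = [chain_and_classify(
                seed_extend_align(q, genome, query_id=f"v{i}"))]
        calls["focal"] = [chain_and_classify(
            seed_extend_align(recombinant.sequence, genome, query_id="focal"))]
        matrix = compare_presence(calls)
        uniq = matrix[matrix["unique_to"] != ""]
        assert set(uniq["unique_to"]) == {"focal"}
        assert len(uniq) == len(calls["focal"][0].breakpoints)
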