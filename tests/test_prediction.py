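"""Exon calling pipeline: mask, merging, filtering, polishing, graph."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exograph.kmers import ExactKmerSet, canonical, canonical_kmers
from exograph.prediction import (
    ExonInterval,
    PredictionParams,
    build_splice_graph,
    filter_short_exons,
    mask_to_intervals,
    merge_close_intervals,
    polish_pair,
    positive_kmer_mask,
    predict_transcript_exons,
)


def solid_from(seqs, k, levels=2):
    s = ExactKmerSet(k=k, levels=levels)
    for seq in seqs:
        for _ in range(levels):
            for _, kmer in canonical_kmers(seq, k):
                s.insert(kmer)
    return s


def iv(start, end, tid="t"):
    return ExonInterval(tid, start, end)


class TestMask:
    def test_all_solid(self):
        s = solid_from(["ACGTACGTAC"], k=4)
        mask = positive_kmer_mask("ACGTACGTAC", s, 4)
        assert mask.all() and mask.size == 7

    def test_none_solid(self):
        s = ExactKmerSet(k=4)
        assert not positive_kmer_mask("ACGTACGTAC", s, 4).any()

    def test_junction_windows_negative(self):
        """Only the k-1 windows spanning the exon junction are negative."""
        exon1, exon2 = "ACCTGAATCA", "TTCAGGACCT"
        k = 4
        s = solid_from([exon1, exon2], k=k)
        tx = exon1 + exon2
        mask = positive_kmer_mask(tx, s, k)
        junction = len(exon1)
        expected = np.ones(len(tx) - k + 1, dtype=bool)
        for p in range(junction - k + 1, junction):
            expected[p] = canonical(tx[p : p + k]) in s.counts and s.is_solid(
                canonical(tx[p : p + k])
            )
        assert (mask == expected).all()
        # and the junction windows really are (mostly) negative
        assert not mask[junction - k + 1 : junction].all()

    def test_short_transcript_empty_mask(self):
        s = ExactKmerSet(k=10)
        assert positive_kmer_mask("ACGT", s, 10).size == 0


class TestMaskToIntervals:
    def test_single_run(self):
        got = mask_to_intervals(np.ones(6, dtype=bool), k=5, transcript_id="t")
        assert got == [iv(0, 10)]

    def test_two_runs_overlap(self):
        mask = np.array([True, True, False, False, True])
        assert mask_to_intervals(mask, k=5, transcript_id="t") == [
            iv(0, 6),
            iv(4, 9),
        ]

    def test_empty(self):
        assert mask_to_intervals(np.zeros(0, dtype=bool), k=5) == []
        assert mask_to_intervals(np.zeros(4, dtype=bool), k=5) == []

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.booleans(), min_size=1, max_size=50),
        st.integers(min_value=1, max_value=8),
    )
    def test_coverage_identity(self, bits, k):
        """The union of intervals equals the union of solid k-mer windows."""
        mask = np.array(bits)
        covered = set()
        for interval in mask_to_intervals(mask, k, "t"):
            covered.update(range(interval.start, interval.end))
        expected = {
            pos
            for p in np.flatnonzero(mask)
            for pos in range(p, p + k)
        }
        assert covered == expected


class TestLengthFilter:
    def test_paper_default_boundary(self):
        """With k=25 and q=5 a 29-base exon is dropped, a 30-base exon kept."""
        out = filter_short_exons([iv(0, 29), iv(50, 80)], k=25, q=5)
        assert out == [iv(50, 80)]

    def test_q_zero_keeps_k_length(self):
        assert filter_short_exons([iv(0, 25)], k=25, q=0) == [iv(0, 25)]
        assert filter_short_exons([], k=25, q=5) == []


class TestRelaxedMerge:
    def test_excessive_overlap_merges(self):
        assert merge_close_intervals([iv(0, 50), iv(38, 100)], 10) == [
            iv(0, 100)
        ]

    def test_tolerated_overlap_kept(self):
        pair = [iv(0, 50), iv(45, 100)]
        assert merge_close_intervals(pair, 10) == pair

    def test_disjoint_untouched(self):
        triple = [iv(0, 50), iv(60, 100), iv(100, 140)]
        assert merge_close_intervals(triple, 10) == triple

    def test_chain_merges_to_fixpoint(self):
        chain = [iv(0, 50), iv(30, 80), iv(60, 110)]
        assert merge_close_intervals(chain, 10) == [iv(0, 110)]


class TestPolish:
    def test_motif_found_and_split(self):
        tx = "A" * 12 + "CCAGGTAA" + "T" * 10
        up, down = polish_pair(iv(0, 20), iv(12, 30), tx)
        assert (up, down) == (iv(0, 16), iv(16, 30))
        assert tx[up.end - 2 : up.end] == "AG"
        assert tx[down.start : down.start + 2] == "GT"

    def test_no_motif_unchanged(self):
        tx = "C" * 30
        pair = (iv(0, 20), iv(12, 30))
        assert polish_pair(*pair, tx) == pair

    def test_motif_at_offset_zero(self):
        tx = "T" * 12 + "AGGT" + "C" * 14
        up, down = polish_pair(iv(0, 20), iv(12, 30), tx)
        assert up.end == down.start == 14

    def test_requires_positive_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            polish_pair(iv(0, 10), iv(10, 20), "A" * 20)


@pytest.fixture(scope="module")
def full_transcript_solid(default_data):
    # every transcript k-mer solid: monotonicity must hold on any input
    return solid_from(list(default_data.transcripts.values()), k=25)


class TestMonotonicity:

    def test_increasing_q_never_adds_exons(self, tx_fasta, full_transcript_solid):
        counts = []
        for q in (0, 5, 20, 80):
            g = build_splice_graph(
                io.StringIO(tx_fasta),
                full_transcript_solid,
                PredictionParams(k=25, q=q),
            )
            counts.append(sum(len(p) for p in g.paths.values()))
        assert counts == sorted(counts, reverse=True)

    def test_increasing_max_overlap_never_adds_exons(
        self, tx_fasta, full_transcript_solid
    ):
        counts = []
        for mo in (0, 5, 10, 30):
            g = build_splice_graph(
                io.StringIO(tx_fasta),
                full_transcript_solid,
                PredictionParams(k=25, max_overlap=mo),
            )
            counts.append(sum(len(p) for p in g.paths.values()))
        assert counts == sorted(counts, reverse=True)


class TestSpliceGraph:
    def test_single_exon_transcript(self):
        seq = "ATCGGATCGTAGCTAGCTAGCATCGATCGAT"
        s = solid_from([seq], k=6)
        g = build_splice_graph(
            io.StringIO(f">t1\n{seq}\n"), s, PredictionParams(k=6, q=0)
        )
        assert list(g.nodes) == ["EXON00000001"]
        assert g.links == {}
        assert g.paths == {"t1": ["EXON00000001"]}
        assert g.nodes["EXON00000001"].sequence == seq

    def test_shared_exons_collapse_into_one_component(self):
        """Two transcripts of one gene sharing exon sequences share nodes."""
        e1 = "ACCTGAATCAGGTCAATTCCAGTCAATAGCAT"
        e2 = "TTCTCGACCTGGATCAATGGCCTTAGGATCAT"
        e3 = "CATTCGAATCGGATCGATTACCGGTTAACCTA"
        t1, t2 = e1 + e2 + e3, e1 + e3
        # solid k-mers come from the exons themselves (as genomic reads
        # would provide); junction-spanning k-mers stay unsolid
        s = solid_from([e1, e2, e3], k=8)
        g = build_splice_graph(
            io.StringIO(f">t1\n{t1}\n>t2\n{t2}\n"),
            s,
            PredictionParams(k=8, q=0),
        )
        # exon sequences shared between transcripts -> shared node ids
        shared = set(g.paths["t1"]) & set(g.paths["t2"])
        assert shared
        # one connected component: every node reachable through links
        adjacency = {n: set() for n in g.nodes}
        for (a, b) in g.links:
            adjacency[a].add(b)
            adjacency[b].add(a)
        seen, stack = set(), [next(iter(g.nodes))]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adjacency[n])
        assert seen == set(g.nodes)

    def test_node_sequence_matches_every_coordinate(
        self, default_data, tx_fasta, exact_solid
    ):
        g = build_splice_graph(
            io.StringIO(tx_fasta), exact_solid, PredictionParams()
        )
        for node in g.nodes.values():
            for (tid, start, end) in node.coordinates:
                assert (
                    default_data.transcripts[tid][start:end] == node.sequence
                )
                assert len(node.sequence) == end - start

    def test_exact_recovery_on_clean_fixture(
        self, default_data, tx_fasta, exact_solid, truth_intervals
    ):
        g = build_splice_graph(
            io.StringIO(tx_fasta), exact_solid, PredictionParams()
        )
        assert sorted(g.intervals()) == sorted(truth_intervals)

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_splice_graph(
                io.StringIO(""), ExactKmerSet(k=25), PredictionParams()
            )

    def test_short_transcript_absent_from_paths(self):
        s = solid_from(["ACGTACGTACGTACGTACGTACGTACGTA"], k=25)
        g = build_splice_graph(
            io.StringIO(">tiny\nACGT\n>ok\nACGTACGTACGTACGTACGTACGTACGTA\n"),
            s,
            PredictionParams(k=25, q=0),
        )
        assert "tiny" not in g.paths and "ok" in g.paths


def test_pipeline_stage_order_matches_contract():
    """Length filter runs before the relaxed merge: a dropped middle exon
    leaves a gap, not a merge."""
    exon1, exon2 = "ACCTGAATCATTCAGGACCTGAATTCCA", "TGGACCATTGGCATCCATTAACCGGTTA"
    k, q = 6, 10
    tx = exon1 + exon2
    s = solid_from([exon1, exon2], k=k)
    intervals = predict_transcript_exons("t", tx, s, PredictionParams(k=k, q=q))
    for interval in intervals:
        assert interval.length >= k + q
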