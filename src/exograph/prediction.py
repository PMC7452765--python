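"""Exon interval calling and splice-graph assembly.

Per transcript the pipeline is: query every canonical k-mer against the
solid set (a); merge runs of positive k-mers overlapping by k-1 bases into
draft exons (b); drop exons shorter than k+q, which are mostly Bloom
false positives (c); re-merge adjacent exons that overlap by more than
``max_overlap`` bases (d); optionally polish remaining overlaps at the
AG-GT splice signal so the upstream exon ends in AG and the downstream
starts with GT (e).  Surviving exons become graph nodes (deduplicated by
sequence), consecutive exons are linked with their signed separation, and
each transcript is recorded as a path (f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from exograph.baiting import ReadSource, iter_fasta
from exograph.kmers import CascadingBloomFilter, ExactKmerSet, canonical_kmers

logger = logging.getLogger(__name__)

SolidBackend = Union[CascadingBloomFilter, ExactKmerSet]

POLISH_MOTIF = "AGGT"


@dataclass(frozen=True, order=True)
class ExonInterval:
    """0-based half-open exon span in transcript coordinates."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) "
                f"on {self.transcript_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PredictionParams:
    """k-mer length, length-filter slack q, relaxed-merge threshold, polish flag."""

    k: int = 25
    q: int = 5
    max_overlap: int = 10
    polish: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.q < 0:
            raise ValueError(f"q must be >= 0, got {self.q}")
        if self.max_overlap < 0:
            raise ValueError(f"max_overlap must be >= 0, got {self.max_overlap}")


@dataclass
class ExonNode:
    sequence: str
    coordinates: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SpliceGraph:
    """Exons as nodes, boundaries as links, transcripts as paths.

    ``links`` maps (upstream_id, downstream_id) to the signed separation in
    transcript space: positive = overlap in bases, 0 = abutting,
    negative = gap.  Node ids are EXON + 8-digit counter in
    first-encounter order.
    """

    nodes: dict[str, ExonNode] = field(default_factory=dict)
    links: dict[tuple[str, str], int] = field(default_factory=dict)
    paths: dict[str, list[str]] = field(default_factory=dict)

    def intervals(self) -> list[ExonInterval]:
        """All recorded exon coordinates as transcript-space intervals."""
        out = [
            ExonInterval(tid, start, end)
            for node in self.nodes.values()
            for (tid, start, end) in node.coordinates
        ]
        return sorted(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpliceGraph):
            return NotImplemented
        if self.links != other.links or self.paths != other.paths:
            return False
        if self.nodes.keys() != other.nodes.keys():
            return False
        return all(
            self.nodes[i].sequence == other.nodes[i].sequence
            and sorted(self.nodes[i].coordinates)
            == sorted(other.nodes[i].coordinates)
            for i in self.nodes
        )


def positive_kmer_mask(
    transcript_seq: str, solid: SolidBackend, k: int
) -> np.ndarray:
    """Boolean vector: position p is True iff the canonical k-mer at p is solid.

    Windows containing non-ACGT characters are False.  A transcript
    shorter than k yields an empty mask.
    """
    n = len(transcript_seq)
    if n < k:
        return np.zeros(0, dtype=bool)
    mask = np.zeros(n - k + 1, dtype=bool)
    for p, kmer in canonical_kmers(transcript_seq, k):
        mask[p] = solid.is_solid(kmer)
    return mask


def mask_to_intervals(
    mask: np.ndarray, k: int, transcript_id: str = ""
) -> list[ExonInterval]:
    """Merge each maximal run of positive k-mers into one interval.

    A run of True positions i..j (k-mers overlapping by k-1 bases) becomes
    the interval [i, j+k).  Intervals from runs separated by short gaps of
    negative k-mers may overlap by up to k-2 bases.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [
        ExonInterval(transcript_id, int(i), int(j) + k - 1)
        for i, j in zip(starts, stops)
    ]


def filter_short_exons(
    intervals: list[ExonInterval], k: int, q: int
) -> list[ExonInterval]:
    """Keep intervals of length >= k + q; shorter ones are likely Bloom noise."""
    return [iv for iv in intervals if iv.length >= k + q]


def merge_close_intervals(
    intervals: list[ExonInterval], max_overlap: int
) -> list[ExonInterval]:
    """Union adjacent intervals overlapping by strictly more than ``max_overlap``.

    Applied left-to-right to fixpoint; overlaps of exactly ``max_overlap``
    or less, abutting pairs and gaps are untouched.
    """
    if not intervals:
        return []
    merged = [intervals[0]]
    for nxt in intervals[1:]:
        prev = merged[-1]
        if prev.end - nxt.start > max_overlap:
            merged[-1] = ExonInterval(
                prev.transcript_id, prev.start, max(prev.end, nxt.end)
            )
        else:
            merged.append(nxt)
    return merged


def polish_pair(
    upstream: ExonInterval, downstream: ExonInterval, transcript_seq: str
) -> tuple[ExonInterval, ExonInterval]:
    """Trim an overlapping exon pair at the AG-GT splice signal.

    Searches the overlap region [downstream.start, upstream.end) for the
    leftmost "AGGT"; the boundary is placed between AG and GT, so the
    upstream exon ends in AG and the downstream starts with GT, removing
    the overlap.  Without the motif the pair is returned unchanged.
    """
    overlap = upstream.end - downstream.start
    if overlap <= 0:
        raise ValueError("polish_pair requires a positive overlap")
    region = transcript_seq[downstream.start : upstream.end].upper()
    i = region.find(POLISH_MOTIF)
    if i == -1:
        return upstream, downstream
    boundary = downstream.start + i + 2
    return (
        ExonInterval(upstream.transcript_id, upstream.start, boundary),
        ExonInterval(downstream.transcript_id, boundary, downstream.end),
    )


def predict_transcript_exons(
    transcript_id: str,
    transcript_seq: str,
    solid: SolidBackend,
    params: PredictionParams,
) -> list[ExonInterval]:
    """Run the per-transcript pipeline: mask, merge, filter, re-merge, polish."""
    mask = positive_kmer_mask(transcript_seq, solid, params.k)
    intervals = mask_to_intervals(mask, params.k, transcript_id)
    intervals = filter_short_exons(intervals, params.k, params.q)
    intervals = merge_close_intervals(intervals, params.max_overlap)
    if params.polish and len(intervals) > 1:
        polished = [intervals[0]]
        for nxt in intervals[1:]:
            prev = polished[-1]
            # motif needs 4 bases of overlap to fit
            if prev.end - nxt.start >= len(POLISH_MOTIF):
                prev, nxt = polish_pair(prev, nxt, transcript_seq)
                polished[-1] = prev
            polished.append(nxt)
        intervals = polished
    return intervals


def build_splice_graph(
    transcriptome: ReadSource,
    solid: SolidBackend,
    params: PredictionParams,
) -> SpliceGraph:
    """Predict exons for every transcript and assemble the splice graph.

    Identical exon sequences from different transcripts collapse into one
    node (case-folded comparison), which makes genes appear as connected
    components.  Consecutive exons are linked with signed separation
    end_i - start_{i+1}; transcripts with no surviving exon are logged and
    absent from the paths.
    """
    graph = SpliceGraph()
    seq_to_id: dict[str, str] = {}
    counter = 0
    n_transcripts = 0
    for rec in iter_fasta(transcriptome):
        n_transcripts += 1
        tid = rec.id
        seq = str(rec.seq).upper()
        if len(seq) < params.k:
            logger.warning(
                "transcript %s shorter than k=%d: no exons", tid, params.k
            )
            continue
        intervals = predict_transcript_exons(tid, seq, solid, params)
        if not intervals:
            logger.info("transcript %s: no exons survived filtering", tid)
            continue
        path = []
        for iv in intervals:
            exon_seq = seq[iv.start : iv.end]
            node_id = seq_to_id.get(exon_seq)
            if node_id is None:
                counter += 1
                node_id = f"EXON{counter:08d}"
                seq_to_id[exon_seq] = node_id
                graph.nodes[node_id] = ExonNode(sequence=exon_seq)
            graph.nodes[node_id].coordinates.append((tid, iv.start, iv.end))
            path.append(node_id)
        for (a, iv_a), (b, iv_b) in zip(
            zip(path, intervals), zip(path[1:], intervals[1:])
        ):
            graph.links.setdefault((a, b), iv_a.end - iv_b.start)
        graph.paths[tid] = path
    if n_transcripts == 0:
        raise ValueError("empty transcriptome")
    logger.info(
        "splice graph: %d exons, %d links, %d paths",
        len(graph.nodes),
        len(graph.links),
        len(graph.paths),
    )
    return graph
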