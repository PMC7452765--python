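"""GFA1 reading/writing and FASTA export of the splice graph.

The dialect: ``H`` header with VN:Z:1.0; one ``S`` line per exon with an
LN:i: length tag; one ``L`` line per boundary, orientations always ``+``
(transcript space is single-stranded), separation encoded as ``oM`` for an
overlap of o bases, ``0M`` for abutting exons, and ``gG`` for a gap of g
bases.  The gap operator is non-standard GFA1 CIGAR but is needed to
represent inter-exon gaps created by the length filter; the parser accepts
it.  One ``C`` line records each (transcript, exon, transcript offset);
one ``P`` line per transcript path.  Record blocks are ordered S, L, C, P,
each in first-encounter order, tab-delimited with LF endings.
"""

from __future__ import annotations

import re
from typing import Iterable

from exograph.prediction import ExonNode, SpliceGraph

_SEP_RE = re.compile(r"^(\d+)([MG])$")
_WRAP = 80


class Gfa1ParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _encode_separation(sep: int) -> str:
    return f"{sep}M" if sep >= 0 else f"{-sep}G"


def _decode_separation(text: str, lineno: int) -> int:
    m = _SEP_RE.match(text)
    if not m:
        raise Gfa1ParseError(f"bad separation string {text!r}", lineno)
    value, op = int(m.group(1)), m.group(2)
    if op == "G" and value == 0:
        raise Gfa1ParseError("gap of zero bases is written as 0M", lineno)
    return value if op == "M" else -value


def write_gfa1(graph: SpliceGraph) -> str:
    """Serialize a splice graph to GFA1 text (dialect above)."""
    for (a, b) in graph.links:
        if a not in graph.nodes or b not in graph.nodes:
            raise ValueError(f"link {a}->{b} references an undeclared exon")
    for tid, path in graph.paths.items():
        for node_id in path:
            if node_id not in graph.nodes:
                raise ValueError(
                    f"path {tid} references undeclared exon {node_id}"
                )
    lines = ["H\tVN:Z:1.0"]
    for node_id, node in graph.nodes.items():
        lines.append(
            f"S\t{node_id}\t{node.sequence}\tLN:i:{len(node.sequence)}"
        )
    for (a, b), sep in graph.links.items():
        lines.append(f"L\t{a}\t+\t{b}\t+\t{_encode_separation(sep)}")
    for node_id, node in graph.nodes.items():
        for (tid, start, end) in node.coordinates:
            lines.append(f"C\t{tid}\t+\t{node_id}\t+\t{start}\t{end - start}M")
    for tid, path in graph.paths.items():
        lines.append(f"P\t{tid}\t{','.join(n + '+' for n in path)}\t*")
    return "\n".join(lines) + "\n"


def read_gfa1(text: str | Iterable[str]) -> SpliceGraph:
    """Parse GFA1 text produced by :func:`write_gfa1`.

    Unknown optional tags are ignored; malformed records, bad separation
    strings and dangling references raise :class:`Gfa1ParseError` with the
    offending line number.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]
    graph = SpliceGraph()
    deferred_links: list[tuple[str, str, int, int]] = []
    deferred_contain: list[tuple[str, str, int, int]] = []
    deferred_paths: list[tuple[str, list[str], int]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        elif tag == "S":
            if len(fields) < 3:
                raise Gfa1ParseError("S line needs id and sequence", lineno)
            node_id, seq = fields[1], fields[2]
            if node_id in graph.nodes:
                raise Gfa1ParseError(f"duplicate segment {node_id}", lineno)
            graph.nodes[node_id] = ExonNode(sequence=seq)
        elif tag == "L":
            if len(fields) < 6:
                raise Gfa1ParseError("L line needs 6 fields", lineno)
            sep = _decode_separation(fields[5], lineno)
            deferred_links.append((fields[1], fields[3], sep, lineno))
        elif tag == "C":
            if len(fields) < 7:
                raise Gfa1ParseError("C line needs 7 fields", lineno)
            try:
                offset = int(fields[5])
            except ValueError:
                raise Gfa1ParseError(f"bad offset {fields[5]!r}", lineno)
            m = _SEP_RE.match(fields[6])
            if not m or m.group(2) != "M":
                raise Gfa1ParseError(f"bad containment CIGAR {fields[6]!r}", lineno)
            deferred_contain.append((fields[1], fields[3], offset, lineno))
        elif tag == "P":
            if len(fields) < 3:
                raise Gfa1ParseError("P line needs name and segment list", lineno)
            segs = []
            for item in fields[2].split(","):
                if not item or item[-1] not in "+-":
                    raise Gfa1ParseError(
                        f"bad path segment {item!r}", lineno
                    )
                segs.append(item[:-1])
            deferred_paths.append((fields[1], segs, lineno))
        else:
            raise Gfa1ParseError(f"unknown record type {tag!r}", lineno)

    for a, b, sep, lineno in deferred_links:
        for node_id in (a, b):
            if node_id not in graph.nodes:
                raise Gfa1ParseError(
                    f"link references undeclared segment {node_id}", lineno
                )
        graph.links[(a, b)] = sep
    for tid, node_id, offset, lineno in deferred_contain:
        node = graph.nodes.get(node_id)
        if node is None:
            raise Gfa1ParseError(
                f"containment references undeclared segment {node_id}", lineno
            )
        node.coordinates.append((tid, offset, offset + len(node.sequence)))
    for tid, segs, lineno in deferred_paths:
        for node_id in segs:
            if node_id not in graph.nodes:
                raise Gfa1ParseError(
                    f"path references undeclared segment {node_id}", lineno
                )
        graph.paths[tid] = segs
    return graph


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + _WRAP] for i in range(0, len(seq), _WRAP))


def exons_to_fasta(graph: SpliceGraph) -> str:
    """One FASTA record per exon node.

    Header: exon id, space, comma-separated ``transcript:start-end``
    coordinate descriptors; sequence wrapped at 80 columns.
    """
    chunks = []
    for node_id, node in graph.nodes.items():
        coords = ",".join(
            f"{tid}:{start}-{end}" for tid, start, end in node.coordinates
        )
        chunks.append(f">{node_id} {coords}\n{_wrap(node.sequence)}\n")
    return "".join(chunks)


def gapped_transcripts_to_fasta(graph: SpliceGraph, n_gap: int = 100) -> str:
    """Transcripts reassembled from their exons, joined by runs of N.

    For links with a positive overlap o the downstream exon's first o
    bases are trimmed before joining, so no sequence is duplicated; with
    n_gap=0 and no filtered bases the original transcript substring is
    reconstructed exactly.
    """
    if n_gap < 0:
        raise ValueError(f"n_gap must be >= 0, got {n_gap}")
    gap = "N" * n_gap
    chunks = []
    for tid, path in graph.paths.items():
        pieces = [graph.nodes[path[0]].sequence]
        for a, b in zip(path, path[1:]):
            sep = graph.links.get((a, b), 0)
            seq = graph.nodes[b].sequence
            if sep > 0:
                seq = seq[sep:]
            pieces.append(seq)
        chunks.append(f">{tid}\n{_wrap(gap.join(pieces))}\n")
    return "".join(chunks)
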