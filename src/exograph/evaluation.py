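"""Annotation-recovery evaluation.

Reference exon annotations live in genome coordinates (GFF3, 1-based
inclusive); predictions live in transcript coordinates.  Conversion stacks
each transcript's exons 5'->3' (ascending genome position on the + strand,
descending on -), so exon lengths accumulate into 0-based half-open
transcript intervals.  Predictions and truths are then matched one-to-one
at >= 95% reciprocal overlap, and precision, recall and F1 summarize the
TP/FP/FN counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

from exograph.prediction import ExonInterval


@dataclass(frozen=True)
class AnnotatedExon:
    """A reference exon in genome coordinates (0-based half-open)."""

    transcript_id: str
    chrom: str
    genome_start: int
    genome_end: int
    strand: str
    rank: int = 0


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _transcript_parent(attrs: dict[str, str]) -> str | None:
    parent = attrs.get("Parent")
    if parent is None:
        return None
    # GFF3 allows multi-parent exons; take the first
    parent = parent.split(",")[0]
    if parent.startswith("transcript:"):
        parent = parent[len("transcript:") :]
    return parent


GffSource = Union[str, Path, IO[str], Iterable[str]]


def _iter_gff_lines(source: GffSource) -> Iterable[str]:
    if isinstance(source, str) and "\n" in source:
        yield from source.splitlines()
        return
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
        return
    yield from source


def read_gff3_exons(source: GffSource) -> list[AnnotatedExon]:
    """Read `exon` features from a GFF3 stream (path, file-like, or lines).

    Only exon rows are consumed; each must carry a ``Parent`` attribute
    naming its transcript (an optional ``transcript:`` prefix is
    stripped).  Coordinates are converted to 0-based half-open.
    """
    exons = []
    for lineno, line in enumerate(_iter_gff_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 fields")
        if fields[2] != "exon":
            continue
        parent = _transcript_parent(_parse_attributes(fields[8]))
        if parent is None:
            raise ValueError(
                f"GFF3 line {lineno}: exon without a transcript Parent"
            )
        strand = fields[6]
        if strand not in "+-":
            raise ValueError(f"GFF3 line {lineno}: bad strand {strand!r}")
        start_1based, end_inclusive = int(fields[3]), int(fields[4])
        exons.append(
            AnnotatedExon(
                transcript_id=parent,
                chrom=fields[0],
                genome_start=start_1based - 1,
                genome_end=end_inclusive,
                strand=strand,
            )
        )
    return exons


def gff3_to_transcript_bed(
    source: GffSource,
) -> dict[str, list[ExonInterval]]:
    """Convert genome-coordinate exon annotations to transcript intervals.

    Exons of each transcript are ordered 5'->3' (by ascending genome
    position on +, descending on -) and their lengths accumulated: exon i
    maps to [c, c + len_i) where c is the summed length of upstream exons.
    The output is BED-like: 0-based half-open with the transcript as the
    reference name.  Mixed strands within a transcript are an error.
    """
    exons = read_gff3_exons(source)
    by_transcript: dict[str, list[AnnotatedExon]] = {}
    for ex in exons:
        by_transcript.setdefault(ex.transcript_id, []).append(ex)

    result: dict[str, list[ExonInterval]] = {}
    for tid, group in by_transcript.items():
        strands = {ex.strand for ex in group}
        if len(strands) > 1:
            raise ValueError(f"transcript {tid} mixes strands {strands}")
        strand = strands.pop()
        ordered = sorted(
            group, key=lambda ex: ex.genome_start, reverse=(strand == "-")
        )
        intervals = []
        cursor = 0
        for ex in ordered:
            length = ex.genome_end - ex.genome_start
            intervals.append(ExonInterval(tid, cursor, cursor + length))
            cursor += length
        result[tid] = intervals
    return result


def _overlap(a: ExonInterval, b: ExonInterval) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def reciprocal_overlap_ok(
    a: ExonInterval, b: ExonInterval, min_frac: float
) -> bool:
    ov = _overlap(a, b)
    if ov <= 0:
        return False
    return ov >= min_frac * a.length and ov >= min_frac * b.length


def classify_predictions(
    pred: list[ExonInterval],
    truth: list[ExonInterval],
    min_frac: float = 0.95,
) -> tuple[int, int, int]:
    """One-to-one matching of predictions to truths at reciprocal overlap.

    A prediction is a TP when some truth interval on the same transcript
    overlaps it by at least ``min_frac`` of BOTH lengths.  Matching is
    greedy by overlap size, ties broken toward the leftmost truth
    interval; each truth matches at most one prediction.  Returns
    (tp, fp, fn).
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    truth_by_tid: dict[str, list[tuple[int, ExonInterval]]] = {}
    for j, t in enumerate(truth):
        truth_by_tid.setdefault(t.transcript_id, []).append((j, t))

    candidates = []  # (-overlap, truth_start, pred_index, truth_index)
    for i, p in enumerate(pred):
        for j, t in truth_by_tid.get(p.transcript_id, []):
            if reciprocal_overlap_ok(p, t, min_frac):
                candidates.append((-_overlap(p, t), t.start, i, j))
    candidates.sort()

    matched_pred: set[int] = set()
    matched_truth: set[int] = set()
    for _, _, i, j in candidates:
        if i in matched_pred or j in matched_truth:
            continue
        matched_pred.add(i)
        matched_truth.add(j)
    tp = len(matched_pred)
    return tp, len(pred) - tp, len(truth) - tp


def prf(tp: int, fp: int, fn: int) -> EvalReport:
    """Precision, recall and F1 from TP/FP/FN counts.

    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); any zero denominator
    yields 0 with the degenerate flag set.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return EvalReport(tp, fp, fn, precision, recall, f1, degenerate)


def evaluate(
    pred: list[ExonInterval],
    truth: list[ExonInterval],
    min_frac: float = 0.95,
) -> EvalReport:
    """Classify and summarize in one call."""
    return prf(*classify_predictions(pred, truth, min_frac))
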