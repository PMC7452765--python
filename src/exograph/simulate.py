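"""Synthetic spliced genome, transcriptome and WGS reads.

The generator emulates the structure the exon-prediction method rests on:
genes whose exons are separated by GT..AG introns, embedded in intergenic
sequence.  Each transcript is the concatenation of its exons, so every
transcript k-mer that spans an exon-exon junction is absent from the
genome -- and therefore from genomic reads -- which is exactly the signal
the Bloom-filter query detects.  A uniqueness filter rejects the rare
genome where a junction-flanking k-mer recurs elsewhere by chance, so
error-free fixtures support exact-recovery tests.

Reads are sampled uniformly from both strands with i.i.d. substitution
errors and constant Phred-40 qualities ('I'); the pipeline ignores
qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from exograph.kmers import canonical, canonical_kmers, reverse_complement
from exograph.prediction import ExonInterval


@dataclass
class GenomeSpec:
    """Layout of the toy genome; all length ranges are inclusive."""

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (200, 500)
    intergenic_len: tuple[int, int] = (300, 600)
    gc: float = 0.5
    seed: int = 42
    minus_strand: bool = False  # alternate gene strands when True

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range {name}={lo, hi}")
        if self.intron_len[0] < 4:
            raise ValueError("introns need >= 4 bases to carry GT..AG")
        if not 0 < self.gc < 1:
            raise ValueError(f"gc must be in (0,1), got {self.gc}")


@dataclass
class ReadSpec:
    """WGS read sampling: fold coverage, read length, errors, pairing."""

    coverage: float = 30.0
    read_len: int = 100
    paired: bool = False
    insert_len: tuple[float, float] = (300.0, 30.0)  # mean, sd
    error_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class Gene:
    gene_id: str
    transcript_id: str
    strand: str
    # genome-coordinate exon spans, 0-based half-open, ascending
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticData:
    chrom: str
    genome: str
    genes: list[Gene]
    transcripts: dict[str, str]
    truth_bed: dict[str, list[ExonInterval]]
    gff3: str

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "transcripts": outdir / "transcripts.fa",
            "gff3": outdir / "annotation.gff3",
            "bed": outdir / "truth.bed",
        }
        paths["genome"].write_text(_fasta_record(self.chrom, self.genome))
        paths["transcripts"].write_text(
            "".join(
                _fasta_record(tid, seq) for tid, seq in self.transcripts.items()
            )
        )
        paths["gff3"].write_text(self.gff3)
        paths["bed"].write_text(
            "".join(
                f"{iv.transcript_id}\t{iv.start}\t{iv.end}\n"
                for ivs in self.truth_bed.values()
                for iv in ivs
            )
        )
        return paths


def _fasta_record(name: str, seq: str, width: int = 80) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{name}\n{body}\n"


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]  # A C G T
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")


def _random_exon(
    rng: np.random.Generator, length: int, gc: float, strand: str
) -> str:
    """Random exon whose transcribed-strand termini are never 'G'.

    A junction-spanning transcript k-mer that overlaps an exon by a single
    base coincides with a genomic k-mer whenever that base equals the
    intron's terminal base (G, from the GT..AG signal), which would blur
    the boundary by one base.  Forbidding G at the transcribed ends of
    each exon removes this systematic ambiguity; boundary placement is
    then exact on error-free data.
    """
    seq = list(_random_seq(rng, length, gc))
    banned = "G" if strand == "+" else "C"  # genome-strand equivalent
    for idx in (0, -1):
        while seq[idx] == banned:
            seq[idx] = _random_seq(rng, 1, gc)
    return "".join(seq)


def _build_once(spec: GenomeSpec, rng: np.random.Generator) -> SyntheticData:
    parts: list[str] = []
    cursor = 0
    genes: list[Gene] = []

    def emit(seq: str) -> None:
        nonlocal cursor
        parts.append(seq)
        cursor += len(seq)

    for g in range(spec.n_genes):
        emit(_random_seq(rng, int(rng.integers(*_incl(spec.intergenic_len))), spec.gc))
        strand = "-" if spec.minus_strand and g % 2 == 1 else "+"
        gene = Gene(
            gene_id=f"gene{g + 1:04d}",
            transcript_id=f"tx{g + 1:04d}",
            strand=strand,
        )
        n_exons = int(rng.integers(*_incl(spec.exons_per_gene)))
        for e in range(n_exons):
            if e > 0:
                ilen = int(rng.integers(*_incl(spec.intron_len)))
                intron = _random_seq(rng, ilen, spec.gc)
                # canonical splice signal in genome + orientation
                intron = "GT" + intron[2:-2] + "AG"
                if strand == "-":
                    # on the - strand the donor/acceptor read GT..AG on
                    # the transcribed strand, i.e. CT..AC on the genome
                    intron = reverse_complement(intron)
                emit(intron)
            elen = int(rng.integers(*_incl(spec.exon_len)))
            start = cursor
            emit(_random_exon(rng, elen, spec.gc, strand))
            gene.exons.append((start, cursor))
        genes.append(gene)
    emit(_random_seq(rng, int(rng.integers(*_incl(spec.intergenic_len))), spec.gc))

    genome = "".join(parts)
    transcripts = {}
    truth_bed: dict[str, list[ExonInterval]] = {}
    for gene in genes:
        exon_seqs = [genome[s:e] for s, e in gene.exons]
        if gene.strand == "-":
            exon_seqs = [reverse_complement(s) for s in reversed(exon_seqs)]
        tx = "".join(exon_seqs)
        transcripts[gene.transcript_id] = tx
        intervals = []
        c = 0
        for seq in exon_seqs:
            intervals.append(
                ExonInterval(gene.transcript_id, c, c + len(seq))
            )
            c += len(seq)
        truth_bed[gene.transcript_id] = intervals

    return SyntheticData(
        chrom="chr1",
        genome=genome,
        genes=genes,
        transcripts=transcripts,
        truth_bed=truth_bed,
        gff3=_render_gff3(genes),
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _render_gff3(genes: list[Gene], chrom: str = "chr1") -> str:
    lines = ["##gff-version 3"]
    for gene in genes:
        gstart = gene.exons[0][0] + 1
        gend = gene.exons[-1][1]
        lines.append(
            f"{chrom}\texograph\tgene\t{gstart}\t{gend}\t.\t{gene.strand}\t."
            f"\tID={gene.gene_id}"
        )
        lines.append(
            f"{chrom}\texograph\tmRNA\t{gstart}\t{gend}\t.\t{gene.strand}\t."
            f"\tID={gene.transcript_id};Parent={gene.gene_id}"
        )
        for i, (s, e) in enumerate(gene.exons, start=1):
            lines.append(
                f"{chrom}\texograph\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t."
                f"\tID={gene.transcript_id}.exon{i};Parent={gene.transcript_id}"
            )
    return "\n".join(lines) + "\n"


def _junctions_unique(data: SyntheticData, k: int) -> bool:
    """True when no junction-spanning transcript k-mer occurs in the genome."""
    genome_kmers = {kmer for _, kmer in canonical_kmers(data.genome, k)}
    for tid, intervals in data.truth_bed.items():
        tx = data.transcripts[tid]
        for iv in intervals[:-1]:
            b = iv.end  # junction position in transcript space
            lo = max(0, b - k + 1)
            hi = min(len(tx) - k, b - 1)
            for p in range(lo, hi + 1):
                if canonical(tx[p : p + k]) in genome_kmers:
                    return False
    return True


def simulate_genome(
    spec: GenomeSpec, k: int = 25, max_attempts: int = 20
) -> SyntheticData:
    """Generate genome, transcripts, GFF3 annotation and truth BED.

    Deterministic under ``spec.seed``.  Genomes where a junction-flanking
    k-mer recurs elsewhere (which would blur the corresponding boundary)
    are rejected and regenerated; with random sequence and k=25 this
    virtually never triggers.
    """
    for attempt in range(max_attempts):
        rng = np.random.default_rng((spec.seed, attempt))
        data = _build_once(spec, rng)
        if _junctions_unique(data, k):
            return data
    raise RuntimeError(
        f"no junction-unique genome found in {max_attempts} attempts"
    )


def _apply_errors(
    read: np.ndarray, rng: np.random.Generator, error_rate: float
) -> np.ndarray:
    if error_rate <= 0:
        return read
    hits = np.flatnonzero(rng.random(read.size) < error_rate)
    if hits.size:
        # shift each hit base by 1-3 positions in ACGT: always a change
        codes = np.searchsorted(_BASES, read[hits])
        shifts = rng.integers(1, 4, size=hits.size)
        read = read.copy()
        read[hits] = _BASES[(codes + shifts) % 4]
    return read


def simulate_reads(
    genome: str | SyntheticData, spec: ReadSpec
) -> tuple[str, ...]:
    """Sample uniform WGS-like reads; returns FASTQ text per mate file.

    Read (fragment, when paired) count is ceil(coverage * genome_len /
    (read_len * mates)), so total sequenced bases match the requested
    coverage.  Each read is reverse-complemented with probability 0.5;
    substitutions are i.i.d. at ``error_rate``.
    """
    if isinstance(genome, SyntheticData):
        genome = genome.genome
    if not genome:
        raise ValueError("empty genome")
    L = len(genome)
    if spec.read_len > L:
        raise ValueError(f"read_len {spec.read_len} exceeds genome length {L}")
    rng = np.random.default_rng(spec.seed)
    garr = np.frombuffer(genome.upper().encode("ascii"), dtype="S1")
    mates = 2 if spec.paired else 1
    n = int(np.ceil(spec.coverage * L / (spec.read_len * mates)))
    qual = "I" * spec.read_len

    def fmt(name: str, seq: np.ndarray) -> str:
        return f"@{name}\n{seq.tobytes().decode('ascii')}\n+\n{qual}\n"

    if not spec.paired:
        chunks = []
        starts = rng.integers(0, L - spec.read_len + 1, size=n)
        flips = rng.random(n) < 0.5
        for i in range(n):
            read = garr[starts[i] : starts[i] + spec.read_len]
            if flips[i]:
                read = _revcomp_arr(read)
            read = _apply_errors(read, rng, spec.error_rate)
            chunks.append(fmt(f"read{i + 1}", read))
        return ("".join(chunks),)

    mean, sd = spec.insert_len
    chunks1, chunks2 = [], []
    for i in range(n):
        insert = int(round(rng.normal(mean, sd)))
        insert = max(spec.read_len, min(insert, L))
        start = int(rng.integers(0, L - insert + 1))
        frag = garr[start : start + insert]
        if rng.random() < 0.5:
            frag = _revcomp_arr(frag)
        r1 = _apply_errors(frag[: spec.read_len], rng, spec.error_rate)
        r2 = _apply_errors(
            _revcomp_arr(frag[-spec.read_len :]), rng, spec.error_rate
        )
        chunks1.append(fmt(f"frag{i + 1}/1", r1))
        chunks2.append(fmt(f"frag{i + 1}/2", r2))
    return ("".join(chunks1), "".join(chunks2))


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _RC[_a] = _b


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _RC[arr.view(np.uint8)][::-1].view("S1")
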