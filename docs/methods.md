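# Methods

## Model

The method assumes the input transcriptome is assembled from the same
individual(s) as the WGS reads, and that introns interrupt transcripts
in the genome. Under those assumptions, a transcript *k*-mer lies in one
of two classes: it is contained in a single exon (and therefore occurs
in the genome and, with adequate coverage, in multiple reads) or it
spans an intron–exon boundary (and occurs in no genomic read at all).
Membership of each transcript *k*-mer in the set of "solid" read
*k*-mers therefore classifies transcript positions as exonic or
boundary-adjacent. Everything else — merging, length filtering, relaxed
merging, polishing — is cleanup of the two error modes: Bloom-filter
false positives (which create spurious positive windows) and low
coverage or sequencing errors (which create spurious negative windows).

Strand is handled by canonicalization: every *k*-mer is represented by
the lexicographic minimum of itself and its reverse complement, so
membership is strand-neutral, as required when reads come from both
strands. Windows containing non-ACGT characters are treated as negative.

## Data structures

**Bloom filter.** A packed bit array of *m* bits probed at *h* positions
per *k*-mer (default *h* = 4). The two 64-bit halves of a
blake2b-128 digest of the canonical *k*-mer seed double hashing,
`pos_i = (h1 + i·h2) mod m` with `h2` forced odd; the scheme is fully
deterministic across runs and platforms, which makes filter files
byte-reproducible. Inserted *k*-mers always query positive; the analytic
false-positive rate is `(1 − e^(−hn/m))^h`, with *n* the number of
insert calls — a proxy for cardinality that over-counts duplicates and
therefore errs on the conservative side.

**Cascading filter.** `levels` Bloom filters of equal size (the total
memory budget split evenly). An insert goes to the first level that does
not already contain the *k*-mer; a *k*-mer is *solid* when the last
level contains it, i.e. it was observed at least `levels` times (up to
Bloom false positives). The default of 2 levels means singleton
*k*-mers — the signature of sequencing errors — are never solid. The
level count is exposed; deeper cascades demand proportionally more
coverage.

**Exact backend.** `ExactKmerSet` implements the same insert/solid
contract with exact counts. It serves as the oracle in tests (solidity
is literally `count ≥ levels`) and as a practical backend at desk scale.
Bloom and exact backends are interchangeable in every pipeline function.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 25 bases | *k*-mer length; smaller boosts recall, larger precision |
| `levels` | 2 | occurrences needed for a *k*-mer to be solid |
| `memory_bits` | CLI: 4 GB equivalent | total cascade bit budget, split across levels |
| `min_shared_kmers` | 1 | transcriptome *k*-mers a read must share to be kept |
| `q` | 5 bases | length-filter slack: exons < *k*+*q* are dropped |
| `max_overlap` | 10 bases | adjacent exons overlapping more than this are merged |
| `polish` | off | trim remaining overlaps at the AG-GT signal |
| `n_gap` | 100 | N-spacer length in gapped transcript FASTA |

The relaxed merge uses a strict inequality (overlap > `max_overlap`
merges, exactly `max_overlap` is kept) and sweeps left-to-right to a
fixpoint. Polishing searches the literal transcript substring of the
overlap region for the leftmost `AGGT` and places the boundary between
`AG` and `GT`; overlaps shorter than the 4-base motif cannot contain it
and are skipped. The donor/acceptor signal is handled in transcript
space (the overlap region), not genome space; only the canonical motif
is recognized — GC-AG and AT-AC introns are out of scope.

## Evaluation conventions

GFF3 input is 1-based inclusive and converted internally to 0-based
half-open; exon order within a transcript follows the strand (ascending
genome coordinate on `+`, descending on `-`), and cumulative exon
lengths give transcript-space intervals. Matching of predictions to
truth intervals is **one-to-one**, greedy by overlap size with ties to
the leftmost truth interval, under a reciprocal-overlap criterion
(≥ 95% of both lengths by default). One-to-one matching guarantees
`TP ≤ min(#pred, #truth)`; tools that count overlap *pairs* can report
more TPs than intervals when predictions nest, so counts are comparable
but not identical to raw `bedtools intersect` pair counts.

## Synthetic data

The generator emulates exactly the structure the method exploits:
i.i.d.-composition genes whose exons are separated by introns carrying
the canonical GT..AG (on the transcribed strand) termini, embedded in
intergenic sequence, with uniformly sampled fixed-length reads carrying
i.i.d. substitution errors and constant Phred-40 qualities. Defaults —
20 genes of 2–4 exons, exons 100–300 bp, introns 200–500 bp, 30×
coverage, 100-bp single-end reads — keep every pipeline stage exercised
while the whole suite runs in seconds; these sizes are this package's
chosen desk-scale study conditions.

Two deliberate idealizations matter for interpreting green tests:

- **Exon termini never carry `G` on the transcribed strand.** A
  junction *k*-mer overlapping an exon by a single base coincides with a
  genomic *k*-mer whenever that base equals the intron's terminal `G`,
  which shifts the detected boundary by a base. Real genomes have such
  junctions (that ambiguity is what polishing addresses); the generator
  excludes them so that exact-recovery tests are exact. A rejection
  filter additionally regenerates any genome where a junction-spanning
  transcript *k*-mer occurs anywhere in the genome by chance.
- **No diploidy, indels, quality structure or alternative splicing.**
  Passing tests demonstrate the combinatorial and probabilistic
  machinery is correct, not that the defaults are optimal for real
  heterozygous data.

Read counts are `ceil(coverage × L / (read_len × mates))` fragments, so
sequenced bases match the requested fold coverage in both single and
paired mode; mates are treated as independent sequences downstream.

## Numerical and degenerate-input choices

- All engine coordinates are 0-based half-open; conversions happen only
  at format boundaries (GFF3 in, FASTA/GFA1 out).
- Transcripts shorter than *k* yield no exons and a warning, not an
  error; transcripts whose exons are all filtered away are logged and
  omitted from graph paths.
- Exon node identity is exact case-folded sequence equality; ids are
  `EXON` + zero-padded counter in first-encounter order, fixed for
  reproducibility. Links are deduplicated on the (upstream, downstream)
  pair, keeping the first-encountered separation.
- Precision/recall/F1 with a zero denominator are defined as 0 and
  flagged degenerate rather than raising.
- Per-level FPR estimates are reported for every cascade level; the
  last level's value is the "analysis FPR" used in comparisons because
  prediction queries only that level.

## Known limitations

- Exons shorter than *k*+*q* (microexons) are invisible by
  construction.
- The Bloom FPR estimate relies on the insert-call count, not true
  cardinality; at extreme duplication it overestimates.
- Boundary placement inherits the one-base ambiguity at junctions whose
  flanking bases mimic intron termini; polishing resolves only cases
  covered by the AG-GT motif.
- Coverage below ~2× the cascade depth leaves true *k*-mers unsolid and
  recall collapses (visible in the 5× vs 30× comparison).
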