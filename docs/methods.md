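# Methods

## The detection model

A read-through (cis-SAGe) event is modelled at the isoform level as a pair of
breakpoints: the last transcribed base of a donor exon of an upstream gene and
the first transcribed base of an acceptor exon of a downstream gene on the
same chromosome and strand. The method assumes (i) the chimeric transcript
splices exactly at annotated exon boundaries — events with novel splice sites
are out of reach by construction; (ii) the two breakpoints lie within a
configurable genomic distance (default 70 kb, the empirical range of
validated read-throughs); and (iii) a supporting read contains the 40-nt
junction string exactly, so sequencing errors or rare variants inside the
40-nt window hide a read (common variants are handled by database expansion,
see below).

Every internal coordinate is 0-based half-open; GTF input (1-based inclusive)
is converted at the loader and reports are emitted 1-based again. Exon rank is
always recomputed from genomic order in transcription direction rather than
trusted from `exon_number` attributes, which keeps the chain invariant under
re-serialization.

Gene pairing requires only same chromosome + strand, transcription-direction
ordering and one eligible exon combination within the distance cap —
adjacency is *not* required, and intervening genes do not disqualify a pair;
the distance rule is applied per exon combination, not per gene span.
Combinations are deduplicated by exon coordinates across transcripts, and
constructed junctions are further collapsed by breakpoint pair, retaining
every contributing (transcript, exon) pair as annotation. Single-exon genes
participate like any other; junctions whose 40-mer contains N are excluded
from the search index (exact matching against N is meaningless) with a logged
count.

## Pre-filters

Filters run in a fixed order for reporting purposes (paralog, flank length,
same-isoform, exon, similarity), but each is a pure per-record predicate
given fixed resources, so the surviving set is order-independent — a property
the test suite asserts by permuting the order. Thresholds: flank 20 bp; exon
filter ≥ 0.90 identity and ≥ 0.90 coverage *of the junction sequence*;
similarity filter ≥ 0.70 identity and ≥ 0.70 coverage *of the probed exon*.
Coverage is always measured over the query (the junction in the exon filter;
the donor/acceptor exon in the similarity filter), and identity over aligned
columns with gap columns counted as non-identical.

The original pipeline used BLAST for the two sequence filters; this package
states them as a local-alignment contract and computes them with a
Smith–Waterman aligner (Biopython `PairwiseAligner`) under blastn-like scores
(match +1, mismatch −2, gap open −5, gap extend −2), probing both the forward
and reverse-complement strand of the subject as a both-strand search would.
An independent brute-force affine-gap DP in the test suite verifies optimal
scores on random sequence pairs. Because alignment-tool internals (word size,
seeding) differ, borderline hits very close to a threshold may be judged
differently than by BLAST itself; the engineered test cases (exact
duplicates, ~50 % identity) are robust to such differences. An exact
containment check short-circuits the aligner where it already decides the
predicate.

In the exon filter no self-hit exclusion is needed: a junction's own
20-nt exon halves can never reach 90 % coverage of a 40-nt query. In the
similarity filter a coordinate-identical partner exon (degenerate overlapping
annotation) is skipped; all other partner-gene exons are probed.

## SNP expansion

Single-nucleotide substitutions with any alternate-allele frequency at or
above the floor (default 0.10) are intersected with the two 20-bp genomic
windows of each surviving junction. One variant record is emitted per
(junction, SNP, qualifying alt): same breakpoints, the single
transcribed-orientation position substituted (complemented on the minus
strand), `variant_of` pointing at the parent. The frequency is interpreted as
the alternate-allele frequency (the VCF CAF/AF convention), not the minor
allele frequency; the floor is a parameter. Combinations of multiple SNPs in
one junction are not enumerated — expansion is linear per SNP — and variants
inherit the parent's filter status rather than re-running the cascade, which
matches inserting variants after filtering. A SNP whose stated reference base
disagrees with the genome is still expanded but logged; an alt that equals
the genome base already in the window is skipped so every variant differs
from its parent at exactly one position.

## Read search

Matching is exact containment of the full 40-mer or its reverse complement,
with no mismatch tolerance and N never acting as a wildcard — fixed-string
semantics. The implementation hashes every junction k-mer (40-mer at the
default flank) and probes each fixed-length window of each read against the
hash; this has the same contract as an Aho–Corasick automaton and its result
is a pure function of (reads, patterns). The pattern set is split into
balanced chunks sized from a user memory budget (a coarse 512 bytes/pattern
estimate — the *semantics* of chunking, not footprint accuracy, is the tested
contract), and chunk×file tasks can run in parallel worker processes; results
are unions, so chunk count, worker count and file order never change the
output. Paired-end mates are independent reads for support counting, with
read IDs normalized to a (fragment, mate) key from `/1 /2` suffixes or
CASAVA-style comments. A read matching the same junction at two offsets
counts once (support is binary per read per junction). FASTA input (e.g.
PacBio long reads) is accepted since the containment test is
read-length-agnostic; reads shorter than the junction length simply cannot
match.

## Post-filters and reporting

Hits are first collapsed to biological events: a parent junction, its SNP
variants and both orientations share one event key (breakpoint pair + gene
pair). Ambiguity is evaluated at this collapsed level — otherwise every
variant hit would disqualify its own read. Reads whose event set has size > 1
are removed in a single pass (surviving reads are unambiguous by
construction, so the pass is a fixed point), support counts are recomputed,
and events left with no reads are dropped. The minimum-supporting-reads
filter is optional (default 1 = identity). Two mates of one fragment
supporting the same event count as two supporting reads; the sidecar file
lists every supporting read so callers can re-aggregate per fragment if they
prefer.

The report is a TSV sorted by (chromosome, donor breakpoint, acceptor
breakpoint) with no timestamps, so identical inputs give byte-identical
output; coordinates are 1-based for browser/primer use and every row's
40-mer is re-derivable from its coordinates and strand (asserted by a
round-trip test). Supporting-read IDs are capped in the table (default 20)
with the complete list in a sidecar; a BEDPE export carries the two
breakpoint anchors.

## Synthetic worlds

The fixture generator emulates exactly what the method consumes: random
uniform-composition chromosomes (50–200 kb scale, a few kb in canned worlds),
block gene layouts with fixed exon/intron sizes, planted read-through truth
events, per-filter decoys (a paralog pair, a 19-bp exon, an overlapping-gene
isoform artifact, a junction 40-mer embedded in an unrelated exon, a
duplicated exon across a gene pair — each isolated on its own chromosome so
stage tallies are exact), planted SNPs (alternate alleles resolved against
the generated genome), and uniform error-free reads from normal plus chimeric
transcripts with random strand and optional pairing. Reads are error-free by
default because the method is exact-match; an optional uniform substitution
rate exists only to demonstrate sensitivity loss. What these worlds do *not*
model: realistic expression distributions, GC/repeat structure, real splice
isoform complexity, quality-score artifacts and platform error profiles — so
passing tests demonstrate the correctness of the machinery on its stated
contract, not sensitivity on real libraries. Problem sizes in tests and the
acceptance script (10-event worlds, ~100–150 reads per transcript, 5–20
random search worlds) were chosen so each stage has overwhelming junction
coverage (at 101-nt reads and depth 120+, the chance a planted junction lacks
a containing read is < 1e-10) while a full run stays in seconds.

## Degenerate inputs and numerical choices

Empty annotation or a zero distance cap yield an empty database and a clean
run; empty alignment queries return a zero-coverage summary; an empty pattern
set yields an empty search plan and no scan. Ties in enumeration and output
are broken by sorted coordinates then lexicographic IDs, making every file
deterministic. The minimum memory budget is one pattern's footprint; below it
the planner raises rather than silently over-chunking.

## Known limitations

Events with breakpoints off annotated exon ends, or farther apart than the
distance cap, are invisible by design. High-error long reads (Nanopore-class)
defeat exact matching. The two alignment filters reproduce thresholds, not
BLAST's exact hit list, near the decision boundary. SNP expansion covers
single common substitutions only — indels and co-occurring variant
combinations are not represented (a pairwise-combination flag is deliberately
absent to keep the database linear in SNP count).
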