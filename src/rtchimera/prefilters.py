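"""Database-side filters that discard potentially false-positive junctions
before the read search.

Five filters run, in order: paralog, flank length, same-isoform, exon,
cross-similarity. Each is a pure predicate given fixed resources, so the final
surviving set is independent of filter order; only the per-stage tallies are
order-sensitive. The two sequence filters replace a BLAST search with local
(Smith-Waterman) alignment under blastn-like scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .annotation_model import (
    Annotation,
    GenomeSequence,
    ParalogRelation,
    exon_sequence,
    reverse_complement,
)
from .junction_db import (
    DEFAULT_FLANK,
    ExonCombination,
    JunctionRecord,
    dedupe_by_breakpoints,
    make_junction,
)

logger = logging.getLogger(__name__)

# blastn-like local alignment scoring
MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -5
GAP_EXTEND = -2

EXON_FILTER_IDENTITY = 0.90
EXON_FILTER_COVERAGE = 0.90
SIMILARITY_IDENTITY = 0.70
SIMILARITY_COVERAGE = 0.70


@dataclass(frozen=True)
class AlignmentSummary:
    """Identity and query coverage of the best local alignment.

    identity = matches / aligned columns (gap columns count as non-identical);
    query_coverage = aligned query bases / query length.
    """

    identity: float
    query_coverage: float
    aligned_length: int

    def passes(self, id_min: float, cov_min: float) -> bool:
        return self.identity >= id_min and self.query_coverage >= cov_min


_ZERO = AlignmentSummary(0.0, 0.0, 0)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def local_align(query: str, subject: str) -> AlignmentSummary:
    """Best local alignment of query against subject (forward strands only)."""
    if not query or not subject:
        return _ZERO
    alignments = _ALIGNER.align(query, subject)
    try:
        best = alignments[0]
    except (IndexError, StopIteration):
        return _ZERO
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return _ZERO
    aligned_query = sum(end - start for start, end in best.aligned[0])
    return AlignmentSummary(
        identity=counts.identities / columns,
        query_coverage=aligned_query / len(query),
        aligned_length=columns,
    )


def best_local_align(query: str, subject: str) -> AlignmentSummary:
    """Best local alignment of query against subject or its reverse complement
    (blastn searches both strands)."""
    fwd = local_align(query, subject)
    rev = local_align(query, reverse_complement(subject))
    return max(fwd, rev, key=lambda s: (s.identity * s.aligned_length))


def _meets(query: str, subject: str, id_min: float, cov_min: float) -> bool:
    # exact containment short-circuits the alignment
    if len(query) <= len(subject) and (
        query in subject or reverse_complement(query) in subject
    ):
        return 1.0 >= id_min and 1.0 >= cov_min
    return (
        local_align(query, subject).passes(id_min, cov_min)
        or local_align(query, reverse_complement(subject)).passes(id_min, cov_min)
    )


# --- filter predicates (True = discard) --------------------------------------


def is_paralog_pair(
    five_gene_id: str, three_gene_id: str, paralogs: ParalogRelation
) -> bool:
    return (five_gene_id, three_gene_id) in paralogs


def flank_too_short(combination: ExonCombination, flank: int = DEFAULT_FLANK) -> bool:
    return combination.donor.length < flank or combination.acceptor.length < flank


def violates_same_isoform(junction: JunctionRecord, annotation: Annotation) -> bool:
    """True iff the junction is a same-isoform artifact of overlapping genes.

    Discard iff an exon with the acceptor's exact coordinates exists in some
    transcript of the 5' gene and immediately follows the donor exon there, or
    an exon with the donor's exact coordinates exists in some transcript of
    the 3' gene and immediately precedes the acceptor exon there.
    """
    donor_c = (junction.donor_exon.start, junction.donor_exon.end)
    accept_c = (junction.acceptor_exon.start, junction.acceptor_exon.end)

    def _adjacent_in(gene_id: str) -> bool:
        gene = annotation.genes.get(gene_id)
        if gene is None:
            return False
        for tx in gene.transcripts.values():
            coords = [(e.start, e.end) for e in tx.exons]
            for i in range(len(coords) - 1):
                if coords[i] == donor_c and coords[i + 1] == accept_c:
                    return True
        return False

    return _adjacent_in(junction.five_gene_id) or _adjacent_in(junction.three_gene_id)


def matches_some_exon(
    junction: JunctionRecord,
    exon_sequences: Sequence[str],
    id_min: float = EXON_FILTER_IDENTITY,
    cov_min: float = EXON_FILTER_COVERAGE,
) -> bool:
    """True iff the junction sequence locally aligns to any annotated exon at
    >= id_min identity covering >= cov_min of the junction sequence. A
    flank-length half can never reach the coverage bound, so no self-hit
    exclusion is needed."""
    return any(
        _meets(junction.sequence, exon_seq, id_min, cov_min)
        for exon_seq in exon_sequences
    )


def cross_similar_exons(
    junction: JunctionRecord,
    annotation: Annotation,
    genome: GenomeSequence,
    id_min: float = SIMILARITY_IDENTITY,
    cov_min: float = SIMILARITY_COVERAGE,
) -> bool:
    """True iff the donor exon resembles some exon of the 3' gene or the
    acceptor exon resembles some exon of the 5' gene (alternative-splicing
    artifacts of a single locus). Coverage is over the probed exon. A
    coordinate-identical partner exon (degenerate overlap) is skipped."""

    def _probe(query_exon, partner_gene_id: str) -> bool:
        gene = annotation.genes.get(partner_gene_id)
        if gene is None:
            return False
        qseq = exon_sequence(query_exon, genome)
        for coords in gene.unique_exon_coords():
            if coords == (query_exon.start, query_exon.end):
                continue
            target = next(
                e for e in gene.exons() if (e.start, e.end) == coords
            )
            if _meets(qseq, exon_sequence(target, genome), id_min, cov_min):
                return True
        return False

    return _probe(junction.donor_exon, junction.three_gene_id) or _probe(
        junction.acceptor_exon, junction.five_gene_id
    )


# --- individual stage transforms ---------------------------------------------


def paralog_filter(
    combinations: Iterable[ExonCombination], paralogs: ParalogRelation
) -> list[ExonCombination]:
    return [
        c
        for c in combinations
        if not is_paralog_pair(c.five_gene.gene_id, c.three_gene.gene_id, paralogs)
    ]


def flank_length_filter(
    combinations: Iterable[ExonCombination], flank: int = DEFAULT_FLANK
) -> list[ExonCombination]:
    return [c for c in combinations if not flank_too_short(c, flank)]


def same_isoform_filter(
    junctions: Iterable[JunctionRecord], annotation: Annotation
) -> list[JunctionRecord]:
    return [j for j in junctions if not violates_same_isoform(j, annotation)]


def exon_filter(
    junctions: Iterable[JunctionRecord],
    exon_sequences: Sequence[str],
    id_min: float = EXON_FILTER_IDENTITY,
    cov_min: float = EXON_FILTER_COVERAGE,
) -> list[JunctionRecord]:
    return [
        j for j in junctions if not matches_some_exon(j, exon_sequences, id_min, cov_min)
    ]


def similarity_filter(
    junctions: Iterable[JunctionRecord],
    annotation: Annotation,
    genome: GenomeSequence,
    id_min: float = SIMILARITY_IDENTITY,
    cov_min: float = SIMILARITY_COVERAGE,
) -> list[JunctionRecord]:
    return [
        j
        for j in junctions
        if not cross_similar_exons(j, annotation, genome, id_min, cov_min)
    ]


# --- the cascade --------------------------------------------------------------


class FilterTally:
    """Per-stage discarded/retained counts; retained_after(f_i) =
    retained_after(f_{i-1}) - discarded(f_i)."""

    def __init__(self, n_input: int):
        self.n_input = n_input
        self.stages: list[tuple[str, int, int]] = []  # (name, discarded, retained)

    def record(self, name: str, before: int, after: int) -> None:
        self.stages.append((name, before - after, after))
        logger.info("%s: discarded %d, retained %d", name, before - after, after)

    def discarded(self, name: str) -> int:
        for stage, discarded, _ in self.stages:
            if stage == name:
                return discarded
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "stages": [
                {"filter": n, "discarded": d, "retained": r}
                for n, d, r in self.stages
            ],
        }


def unique_exon_sequences(
    annotation: Annotation, genome: GenomeSequence
) -> list[str]:
    """All distinct annotated exon sequences (transcribed orientation)."""
    seen: dict[tuple, str] = {}
    for exon in annotation.all_exons():
        key = (exon.chrom, exon.start, exon.end, exon.strand)
        if key not in seen:
            seen[key] = exon_sequence(exon, genome)
    return [seen[k] for k in sorted(seen)]


def run_prefilter_cascade(
    combinations: Iterable[ExonCombination],
    annotation: Annotation,
    genome: GenomeSequence,
    paralogs: ParalogRelation,
    flank: int = DEFAULT_FLANK,
    exon_id_min: float = EXON_FILTER_IDENTITY,
    exon_cov_min: float = EXON_FILTER_COVERAGE,
    sim_id_min: float = SIMILARITY_IDENTITY,
    sim_cov_min: float = SIMILARITY_COVERAGE,
) -> tuple[list[JunctionRecord], FilterTally]:
    """Apply the five pre-filters in order and build the surviving junctions.

    The paralog and flank-length filters act on exon combinations (the latter
    is a constructibility constraint); survivors are built into junction
    records, deduplicated by breakpoint pair, then passed through the
    same-isoform, exon and similarity filters.
    """
    combos = list(combinations)
    tally = FilterTally(len(combos))

    n0 = len(combos)
    combos = paralog_filter(combos, paralogs)
    tally.record("paralog", n0, len(combos))

    n1 = len(combos)
    combos = flank_length_filter(combos, flank)
    tally.record("flank_length", n1, len(combos))

    junctions = dedupe_by_breakpoints(
        make_junction(c, genome, flank) for c in combos
    )

    n2 = len(junctions)
    junctions = same_isoform_filter(junctions, annotation)
    tally.record("same_isoform", n2, len(junctions))

    exon_seqs = unique_exon_sequences(annotation, genome)
    n3 = len(junctions)
    junctions = exon_filter(junctions, exon_seqs, exon_id_min, exon_cov_min)
    tally.record("exon", n3, len(junctions))

    n4 = len(junctions)
    junctions = similarity_filter(junctions, annotation, genome, sim_id_min, sim_cov_min)
    tally.record("similarity", n4, len(junctions))

    return junctions, tally
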