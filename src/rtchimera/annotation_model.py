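"""Genome, gene annotation and paralog relation as a queryable in-memory model.

Coordinate convention: every interval in this package is 0-based half-open
``[start, end)`` on the forward genomic strand. GTF input (1-based inclusive)
is converted at the I/O boundary; breakpoints in reports are emitted 1-based
for genome-browser use. Nothing outside the loaders and the report writer
should ever see a 1-based coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


class GenomeSequence:
    """Uppercase, bounds-checked accessor over a FASTA genome.

    Records are addressable by the first whitespace-delimited token of their
    FASTA header. Slices are 0-based half-open and must lie within the
    chromosome; the returned string always has exactly the requested length.
    """

    def __init__(self, fasta_path: str):
        try:
            self._fasta = Fasta(
                str(fasta_path), as_raw=True, sequence_always_upper=True
            )
        except Exception as exc:  # pyfaidx raises several types
            raise AnnotationError(f"cannot read FASTA {fasta_path}: {exc}") from exc
        if len(self._fasta.keys()) == 0:
            raise AnnotationError(f"FASTA {fasta_path} contains no records")

    def chromosomes(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[chrom][start:end] (0-based half-open, forward strand)."""
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"slice [{start},{end}) outside chromosome {chrom} of length {n}"
            )
        seq = str(self._fasta[chrom][start:end])
        assert len(seq) == end - start
        return seq


def load_genome(fasta_path: str) -> GenomeSequence:
    """Open a FASTA genome for random access (an .fai index is created)."""
    return GenomeSequence(fasta_path)


@dataclass(frozen=True)
class Exon:
    """One exon of one transcript; ``rank`` is 1-based in transcription order."""

    exon_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self):
        if self.end <= self.start:
            raise AnnotationError(
                f"exon {self.exon_id}: end {self.end} <= start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: tuple[Exon, ...]  # transcription order (rank 1..n)


@dataclass
class Gene:
    gene_id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def exons(self) -> Iterator[Exon]:
        """All exons over all transcripts (duplicated coordinates kept per-transcript)."""
        for tx in self.transcripts.values():
            yield from tx.exons

    def unique_exon_coords(self) -> list[tuple[int, int]]:
        """Distinct (start, end) exon intervals, sorted."""
        return sorted({(e.start, e.end) for e in self.exons()})


class Annotation:
    """All genes of an annotation, with strand-ordered exon chains."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str, strand: str) -> list[Gene]:
        out = [
            g for g in self.genes.values() if g.chrom == chrom and g.strand == strand
        ]
        out.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out

    def chrom_strand_pairs(self) -> list[tuple[str, str]]:
        return sorted({(g.chrom, g.strand) for g in self.genes.values()})

    def all_exons(self) -> Iterator[Exon]:
        for g in sorted(self.genes.values(), key=lambda g: g.gene_id):
            yield from g.exons()


def load_annotation(gtf_path: str) -> Annotation:
    """Load exon features from an Ensembl-dialect GTF into an Annotation.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention here and only here. Exon rank is recomputed from
    genomic order in transcription direction (ascending coordinate on ``+``,
    descending on ``-``), so it is consistent whether or not the file carries
    an ``exon_number`` attribute. Exons lacking gene_id or transcript_id are
    skipped with a warning; mixed strands within one gene are an error.
    """
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise AnnotationError(f"cannot parse GTF {gtf_path}: {exc}") from exc

    # (gene_id, transcript_id) -> list of raw exon tuples
    raw: dict[tuple[str, str], list] = {}
    gene_meta: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id", [])
        tx_ids = feat.attributes.get("transcript_id", [])
        if not gene_ids or not tx_ids:
            logger.warning(
                "skipping exon at %s:%d-%d lacking gene_id/transcript_id",
                feat.seqid, feat.start, feat.end,
            )
            continue
        gene_id, tx_id = gene_ids[0], tx_ids[0]
        start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        exon_id = feat.attributes.get("exon_id", [f"{tx_id}.e{start0}"])[0]
        name = feat.attributes.get("gene_name", [gene_id])[0]
        meta = gene_meta.setdefault(
            gene_id, {"name": name, "chrom": feat.seqid, "strand": feat.strand}
        )
        if meta["strand"] != feat.strand or meta["chrom"] != feat.seqid:
            raise AnnotationError(
                f"gene {gene_id}: exons on mixed strands/chromosomes"
            )
        raw.setdefault((gene_id, tx_id), []).append((start0, end0, exon_id))

    genes: dict[str, Gene] = {}
    for (gene_id, tx_id), exon_tuples in raw.items():
        meta = gene_meta[gene_id]
        strand = meta["strand"]
        exon_tuples.sort(key=lambda t: t[0], reverse=(strand == "-"))
        exons = tuple(
            Exon(
                exon_id=eid,
                gene_id=gene_id,
                transcript_id=tx_id,
                chrom=meta["chrom"],
                start=s,
                end=e,
                strand=strand,
                rank=i + 1,
            )
            for i, (s, e, eid) in enumerate(exon_tuples)
        )
        gene = genes.get(gene_id)
        if gene is None:
            gene = Gene(
                gene_id=gene_id,
                name=meta["name"],
                chrom=meta["chrom"],
                strand=strand,
                start=min(e.start for e in exons),
                end=max(e.end for e in exons),
            )
            genes[gene_id] = gene
        gene.transcripts[tx_id] = Transcript(tx_id, gene_id, exons)
        gene.start = min(gene.start, min(e.start for e in exons))
        gene.end = max(gene.end, max(e.end for e in exons))

    return Annotation(genes)


class ParalogRelation:
    """Symmetric, irreflexive relation over gene IDs (membership test only)."""

    def __init__(self, pairs: set[frozenset[str]] | None = None):
        self._pairs: set[frozenset[str]] = set(pairs or set())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise AnnotationError(f"self-paralog pair {a!r}")
        self._pairs.add(frozenset((a, b)))


def load_paralogs(tsv_path: str) -> ParalogRelation:
    """Read a two-column TSV of paralogous gene-ID pairs (header optional).

    A header line is recognised by a first field that is not repeated later;
    in practice we accept any first line and simply skip it if its two fields
    equal each other case-insensitively to common header words.
    """
    rel = ParalogRelation()
    header_words = {"gene_id", "gene", "paralog", "gene1", "gene2", "id"}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise AnnotationError(
                    f"{tsv_path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            a, b = fields
            if lineno == 1 and (a.lower() in header_words or b.lower() in header_words):
                continue
            if a == b:
                continue  # self-pairs carry no information for the filter
            rel.add(a, b)
    return rel


def exon_sequence(exon: Exon, genome: GenomeSequence) -> str:
    """Exon sequence in transcribed orientation (revcomp of genomic on ``-``)."""
    seq = genome.fetch(exon.chrom, exon.start, exon.end)
    return reverse_complement(seq) if exon.strand == "-" else seq
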