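"""Enumeration of candidate gene pairs / exon combinations and construction of
the junction-sequence database.

A read-through (cis-SAGe) junction joins the last transcribed base of an exon
of an upstream gene (the donor breakpoint) to the first transcribed base of an
exon of a downstream same-strand gene (the acceptor breakpoint). Its searchable
signature is the 2*flank-nt string made of the ``flank`` transcribed bases
ending at the donor breakpoint followed by the ``flank`` transcribed bases
starting at the acceptor breakpoint (40 nt at the default flank of 20).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .annotation_model import (
    Annotation,
    Exon,
    Gene,
    GenomeSequence,
    reverse_complement,
)

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20
DEFAULT_MAX_DISTANCE = 70_000

FORWARD = "forward"
REVCOMP = "revcomp"


class FlankTooShort(ValueError):
    """An exon is shorter than the requested flank; no junction can be built."""


@dataclass(frozen=True)
class Breakpoint:
    """A 1-based genomic coordinate of a terminal exonic base."""

    chrom: str
    position: int
    strand: str


def donor_breakpoint(exon: Exon) -> Breakpoint:
    """Last transcribed base of the donor exon (1-based genomic)."""
    pos = exon.end if exon.strand == "+" else exon.start + 1
    return Breakpoint(exon.chrom, pos, exon.strand)


def acceptor_breakpoint(exon: Exon) -> Breakpoint:
    """First transcribed base of the acceptor exon (1-based genomic)."""
    pos = exon.start + 1 if exon.strand == "+" else exon.end
    return Breakpoint(exon.chrom, pos, exon.strand)


@dataclass(frozen=True)
class ExonCombination:
    """One donor/acceptor exon coordinate pair for a candidate gene pair.

    Combinations are deduplicated by exon coordinates; the transcript/exon IDs
    of every contributing copy are retained in ``donor_sources`` /
    ``acceptor_sources``.
    """

    five_gene: Gene
    three_gene: Gene
    donor: Exon
    acceptor: Exon
    donor_sources: tuple[tuple[str, str], ...] = ()  # (transcript_id, exon_id)
    acceptor_sources: tuple[tuple[str, str], ...] = ()

    @property
    def distance(self) -> int:
        return abs(acceptor_breakpoint(self.acceptor).position
                   - donor_breakpoint(self.donor).position)


@dataclass
class JunctionRecord:
    """One junction: a donor/acceptor breakpoint pair with its sequence."""

    junction_id: str
    five_gene_id: str
    five_gene_name: str
    three_gene_id: str
    three_gene_name: str
    chrom: str
    strand: str
    donor_exon: Exon
    acceptor_exon: Exon
    donor_bp: Breakpoint
    acceptor_bp: Breakpoint
    sequence: str
    distance: int
    flank: int = DEFAULT_FLANK
    variant_of: str | None = None
    snp_ids: tuple[str, ...] = ()
    donor_sources: tuple[tuple[str, str], ...] = ()
    acceptor_sources: tuple[tuple[str, str], ...] = ()
    contains_n: bool = field(default=False)

    @property
    def event_key(self) -> tuple:
        """Breakpoint-pair identity of the biological event (variants collapse)."""
        return (
            self.chrom,
            self.strand,
            self.donor_bp.position,
            self.acceptor_bp.position,
            self.five_gene_id,
            self.three_gene_id,
        )


def _is_downstream(donor_bp: Breakpoint, acceptor_bp: Breakpoint, strand: str) -> bool:
    """True iff the acceptor breakpoint lies strictly downstream (transcription
    direction) of the donor breakpoint."""
    if strand == "+":
        return acceptor_bp.position > donor_bp.position
    return acceptor_bp.position < donor_bp.position


def _upstream(a: Gene, b: Gene) -> bool:
    """True iff gene ``a`` starts upstream of gene ``b`` in transcription direction."""
    if a.strand == "+":
        return (a.start, a.end) < (b.start, b.end)
    return (a.end, a.start) > (b.end, b.start)


def enumerate_exon_combinations(
    five_gene: Gene,
    three_gene: Gene,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> Iterator[ExonCombination]:
    """All eligible (donor, acceptor) exon coordinate pairs for a gene pair.

    Eligibility: acceptor breakpoint strictly downstream of the donor
    breakpoint, and unsigned genomic breakpoint distance <= max_distance.
    Exons identical by coordinates across transcripts yield one combination,
    with every contributing (transcript, exon) retained.
    """
    strand = five_gene.strand

    def _by_coords(gene: Gene) -> dict[tuple[int, int], list[Exon]]:
        out: dict[tuple[int, int], list[Exon]] = {}
        for e in gene.exons():
            out.setdefault((e.start, e.end), []).append(e)
        return out

    donors = _by_coords(five_gene)
    acceptors = _by_coords(three_gene)
    for dcoords in sorted(donors):
        dex = donors[dcoords][0]
        dbp = donor_breakpoint(dex)
        for acoords in sorted(acceptors):
            aex = acceptors[acoords][0]
            abp = acceptor_breakpoint(aex)
            if not _is_downstream(dbp, abp, strand):
                continue
            if abs(abp.position - dbp.position) > max_distance:
                continue
            yield ExonCombination(
                five_gene=five_gene,
                three_gene=three_gene,
                donor=dex,
                acceptor=aex,
                donor_sources=tuple(
                    (e.transcript_id, e.exon_id) for e in donors[dcoords]
                ),
                acceptor_sources=tuple(
                    (e.transcript_id, e.exon_id) for e in acceptors[acoords]
                ),
            )


def enumerate_candidate_pairs(
    annotation: Annotation,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> Iterator[tuple[Gene, Gene]]:
    """Stream (5' gene, 3' gene) pairs on the same chromosome and strand with
    the 5' gene upstream, emitted iff at least one donor/acceptor exon
    combination satisfies the distance rule. Intervening genes do not
    disqualify a pair; gene adjacency is not required.
    """
    for chrom, strand in annotation.chrom_strand_pairs():
        genes = annotation.genes_on(chrom, strand)
        for i, a in enumerate(genes):
            for b in genes[i + 1:] + genes[:i]:
                if a.gene_id == b.gene_id:
                    continue
                if not _upstream(a, b):
                    continue
                # cheap span-gap prune before the per-exon check
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap > max_distance:
                    continue
                if next(
                    enumerate_exon_combinations(a, b, max_distance), None
                ) is not None:
                    yield (a, b)


def make_junction(
    combination: ExonCombination,
    genome: GenomeSequence,
    flank: int = DEFAULT_FLANK,
) -> JunctionRecord:
    """Build the junction record for one exon combination.

    The sequence is the last ``flank`` transcribed bases of the donor exon
    followed by the first ``flank`` transcribed bases of the acceptor exon; on
    the minus strand both windows are reverse-complemented genomic slices.
    """
    donor, acceptor = combination.donor, combination.acceptor
    if donor.length < flank:
        raise FlankTooShort(
            f"donor exon {donor.exon_id} length {donor.length} < flank {flank}"
        )
    if acceptor.length < flank:
        raise FlankTooShort(
            f"acceptor exon {acceptor.exon_id} length {acceptor.length} < flank {flank}"
        )
    strand = donor.strand
    if strand == "+":
        donor_win = genome.fetch(donor.chrom, donor.end - flank, donor.end)
        accept_win = genome.fetch(acceptor.chrom, acceptor.start, acceptor.start + flank)
        seq = donor_win + accept_win
    else:
        donor_win = genome.fetch(donor.chrom, donor.start, donor.start + flank)
        accept_win = genome.fetch(acceptor.chrom, acceptor.end - flank, acceptor.end)
        seq = reverse_complement(donor_win) + reverse_complement(accept_win)
    dbp = donor_breakpoint(donor)
    abp = acceptor_breakpoint(acceptor)
    jid = (
        f"{combination.five_gene.gene_id}:{dbp.position}"
        f"|{combination.three_gene.gene_id}:{abp.position}"
    )
    return JunctionRecord(
        junction_id=jid,
        five_gene_id=combination.five_gene.gene_id,
        five_gene_name=combination.five_gene.name,
        three_gene_id=combination.three_gene.gene_id,
        three_gene_name=combination.three_gene.name,
        chrom=donor.chrom,
        strand=strand,
        donor_exon=donor,
        acceptor_exon=acceptor,
        donor_bp=dbp,
        acceptor_bp=abp,
        sequence=seq,
        distance=abs(abp.position - dbp.position),
        flank=flank,
        donor_sources=combination.donor_sources,
        acceptor_sources=combination.acceptor_sources,
        contains_n="N" in seq,
    )


def dedupe_by_breakpoints(junctions: Iterable[JunctionRecord]) -> list[JunctionRecord]:
    """Collapse junctions sharing a breakpoint pair, merging contributing sources."""
    by_key: dict[tuple, JunctionRecord] = {}
    for j in junctions:
        prev = by_key.get(j.event_key)
        if prev is None:
            by_key[j.event_key] = j
        else:
            by_key[j.event_key] = replace(
                prev,
                donor_sources=tuple(
                    dict.fromkeys(prev.donor_sources + j.donor_sources)
                ),
                acceptor_sources=tuple(
                    dict.fromkeys(prev.acceptor_sources + j.acceptor_sources)
                ),
            )
    return [by_key[k] for k in sorted(by_key)]


class SequenceIndex:
    """Map from unique junction k-mer to the set of (junction_id, orientation)
    pairs it identifies. Every junction contributes its sequence and its
    reverse complement; a palindromic sequence contributes a single key
    carrying both orientations.
    """

    def __init__(self):
        self._map: dict[str, set[tuple[str, str]]] = {}
        self.n_excluded_n = 0

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._map

    def lookup(self, kmer: str) -> frozenset[tuple[str, str]]:
        return frozenset(self._map.get(kmer, ()))

    def patterns(self) -> list[str]:
        return sorted(self._map)

    def pattern_lengths(self) -> set[int]:
        return {len(p) for p in self._map}

    def add(self, junction: JunctionRecord) -> None:
        if junction.contains_n:
            self.n_excluded_n += 1
            return
        self._map.setdefault(junction.sequence, set()).add(
            (junction.junction_id, FORWARD)
        )
        self._map.setdefault(reverse_complement(junction.sequence), set()).add(
            (junction.junction_id, REVCOMP)
        )


def build_index(junctions: Iterable[JunctionRecord]) -> SequenceIndex:
    """Index every junction (and every SNP variant) under both orientations."""
    idx = SequenceIndex()
    for j in junctions:
        idx.add(j)
    if idx.n_excluded_n:
        logger.info(
            "excluded %d junction sequences containing N from the index",
            idx.n_excluded_n,
        )
    return idx


# --- database serialization -------------------------------------------------

_DB_COLUMNS = [
    "junction_id", "five_gene_id", "five_gene_name", "three_gene_id",
    "three_gene_name", "chrom", "strand",
    "donor_exon_start", "donor_exon_end", "donor_breakpoint",
    "acceptor_exon_start", "acceptor_exon_end", "acceptor_breakpoint",
    "distance", "flank", "sequence", "variant_of", "snp_ids",
    "donor_sources", "acceptor_sources",
]


def write_junction_db(
    junctions: Iterable[JunctionRecord],
    tsv_path: str,
    manifest_path: str | None = None,
    manifest: dict | None = None,
) -> None:
    """Serialize the junction database as TSV plus an optional JSON manifest."""
    rows = sorted(
        junctions,
        key=lambda j: (j.chrom, j.donor_bp.position, j.acceptor_bp.position,
                       j.junction_id),
    )
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_DB_COLUMNS) + "\n")
        for j in rows:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        j.junction_id, j.five_gene_id, j.five_gene_name,
                        j.three_gene_id, j.three_gene_name, j.chrom, j.strand,
                        j.donor_exon.start, j.donor_exon.end, j.donor_bp.position,
                        j.acceptor_exon.start, j.acceptor_exon.end,
                        j.acceptor_bp.position, j.distance, j.flank, j.sequence,
                        j.variant_of or ".",
                        ",".join(j.snp_ids) or ".",
                        ";".join(f"{t}:{e}" for t, e in j.donor_sources) or ".",
                        ";".join(f"{t}:{e}" for t, e in j.acceptor_sources) or ".",
                    )
                )
                + "\n"
            )
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest or {}, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_junction_db(tsv_path: str) -> list[JunctionRecord]:
    """Read back a junction database TSV written by :func:`write_junction_db`."""
    out: list[JunctionRecord] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DB_COLUMNS:
            raise ValueError(f"{tsv_path}: unexpected junction DB header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = dict(zip(_DB_COLUMNS, f))
            strand = row["strand"]
            flank = int(row["flank"])
            donor = Exon(
                exon_id=f"{row['junction_id']}.donor",
                gene_id=row["five_gene_id"],
                transcript_id=".",
                chrom=row["chrom"],
                start=int(row["donor_exon_start"]),
                end=int(row["donor_exon_end"]),
                strand=strand,
                rank=1,
            )
            acceptor = Exon(
                exon_id=f"{row['junction_id']}.acceptor",
                gene_id=row["three_gene_id"],
                transcript_id=".",
                chrom=row["chrom"],
                start=int(row["acceptor_exon_start"]),
                end=int(row["acceptor_exon_end"]),
                strand=strand,
                rank=1,
            )
            out.append(
                JunctionRecord(
                    junction_id=row["junction_id"],
                    five_gene_id=row["five_gene_id"],
                    five_gene_name=row["five_gene_name"],
                    three_gene_id=row["three_gene_id"],
                    three_gene_name=row["three_gene_name"],
                    chrom=row["chrom"],
                    strand=strand,
                    donor_exon=donor,
                    acceptor_exon=acceptor,
                    donor_bp=Breakpoint(row["chrom"], int(row["donor_breakpoint"]), strand),
                    acceptor_bp=Breakpoint(
                        row["chrom"], int(row["acceptor_breakpoint"]), strand
                    ),
                    sequence=row["sequence"],
                    distance=int(row["distance"]),
                    flank=flank,
                    variant_of=None if row["variant_of"] == "." else row["variant_of"],
                    snp_ids=tuple(
                        row["snp_ids"].split(",")
                    ) if row["snp_ids"] != "." else (),
                    contains_n="N" in row["sequence"],
                )
            )
    return out
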