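"""Seeded synthetic test worlds: toy genome, annotation, paralog table, SNP
table, planted read-through truth set and simulated reads.

Worlds are fully synthetic and generated programmatically; the same seed
always yields byte-identical files. Decoy builders engineer exactly one victim
per pre-filter so the whole cascade is exercised without any external data.
Reads are error-free by default: the detection method is exact-match, so an
error model only demonstrates sensitivity loss.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np

from .annotation_model import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneSpec:
    """Gene layout; exons are 0-based half-open genomic intervals in ascending
    genomic order. ``transcripts`` maps transcript suffixes to tuples of exon
    indices (genomic order); None means one transcript over all exons."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcripts: dict[str, tuple[int, ...]] | None = None

    def transcript_map(self) -> dict[str, tuple[int, ...]]:
        if self.transcripts is not None:
            return self.transcripts
        return {"t1": tuple(range(len(self.exons)))}

    def tx_order(self, exon_indices: tuple[int, ...]) -> list[tuple[int, int]]:
        """Exon intervals in transcription order."""
        coords = [self.exons[i] for i in exon_indices]
        coords.sort(key=lambda c: c[0], reverse=(self.strand == "-"))
        return coords


@dataclass(frozen=True)
class SnpSpec:
    """A planted SNP; an empty ``alt`` is resolved against the generated genome
    (the base after the reference in ACGT cycle order) when the world is built."""

    chrom: str
    pos: int  # 1-based
    snp_id: str
    alt: str
    caf: float


@dataclass(frozen=True)
class PlantedEvent:
    """A true read-through: exon indices are 0-based in transcription order."""

    five_gene: str
    three_gene: str
    donor_exon: int
    acceptor_exon: int


@dataclass(frozen=True)
class SequencePlant:
    """Overwrite genome bases at (chrom, start) with an engineered sequence.

    kind 'literal': payload is the sequence; kind 'exon_copy': payload is
    (gene_id, genomic exon index); kind 'junction_copy': payload is
    (five_gene, three_gene, donor_tx_idx, acceptor_tx_idx, flank)."""

    chrom: str
    start: int
    kind: str
    payload: tuple | str


@dataclass
class FixtureSpec:
    seed: int
    chromosomes: dict[str, int]
    genes: list[GeneSpec] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    snps: list[SnpSpec] = field(default_factory=list)
    events: list[PlantedEvent] = field(default_factory=list)
    plants: list[SequencePlant] = field(default_factory=list)


@dataclass(frozen=True)
class TruthRow:
    five_gene: str
    three_gene: str
    chrom: str
    strand: str
    donor_breakpoint: int  # 1-based
    acceptor_breakpoint: int
    donor_exon: int  # transcription-order index
    acceptor_exon: int


@dataclass
class World:
    spec: FixtureSpec
    outdir: str
    fasta: str
    gtf: str
    paralogs_tsv: str
    snps_tsv: str
    truth_tsv: str
    chrom_seqs: dict[str, str]
    truth: list[TruthRow]
    snps: list[SnpSpec] = field(default_factory=list)  # alt alleles resolved

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.spec.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _tx_exon(gene: GeneSpec, tx_index: int) -> tuple[int, int]:
    """Exon interval at a transcription-order index over all exons of the gene."""
    return gene.tx_order(tuple(range(len(gene.exons))))[tx_index]


def event_breakpoints(
    five: GeneSpec, three: GeneSpec, donor_idx: int, acceptor_idx: int
) -> tuple[int, int]:
    """1-based donor/acceptor breakpoints of a planted event."""
    d = _tx_exon(five, donor_idx)
    a = _tx_exon(three, acceptor_idx)
    strand = five.strand
    donor_bp = d[1] if strand == "+" else d[0] + 1
    acceptor_bp = a[0] + 1 if strand == "+" else a[1]
    return donor_bp, acceptor_bp


def _junction_seq(
    chrom_seqs: dict[str, str],
    five: GeneSpec,
    three: GeneSpec,
    donor_idx: int,
    acceptor_idx: int,
    flank: int = 20,
) -> str:
    d = _tx_exon(five, donor_idx)
    a = _tx_exon(three, acceptor_idx)
    seq = chrom_seqs[five.chrom]
    if five.strand == "+":
        return seq[d[1] - flank: d[1]] + seq[a[0]: a[0] + flank]
    return reverse_complement(seq[d[0]: d[0] + flank]) + reverse_complement(
        seq[a[1] - flank: a[1]]
    )


def generate_world(spec: FixtureSpec, outdir: str) -> World:
    """Write FASTA/GTF/paralog TSV/SNP TSV/truth TSV for a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    os.makedirs(outdir, exist_ok=True)

    chrom_seqs = {
        name: _random_seq(rng, length)
        for name, length in spec.chromosomes.items()
    }

    for gene in spec.genes:
        if gene.chrom not in chrom_seqs:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        clen = len(chrom_seqs[gene.chrom])
        for s, e in gene.exons:
            if not (0 <= s < e <= clen):
                raise ValueError(
                    f"gene {gene.gene_id}: exon [{s},{e}) outside {gene.chrom}"
                )

    genes_by_id = {g.gene_id: g for g in spec.genes}
    for plant in spec.plants:
        if plant.kind == "literal":
            ins = str(plant.payload)
        elif plant.kind == "exon_copy":
            gid, idx = plant.payload  # type: ignore[misc]
            g = genes_by_id[gid]
            s, e = g.exons[idx]
            ins = chrom_seqs[g.chrom][s:e]
        elif plant.kind == "junction_copy":
            fg, tg, didx, aidx, flank = plant.payload  # type: ignore[misc]
            ins = _junction_seq(
                chrom_seqs, genes_by_id[fg], genes_by_id[tg], didx, aidx, flank
            )
        else:
            raise ValueError(f"unknown plant kind {plant.kind!r}")
        seq = chrom_seqs[plant.chrom]
        if plant.start < 0 or plant.start + len(ins) > len(seq):
            raise ValueError(f"plant at {plant.chrom}:{plant.start} out of bounds")
        chrom_seqs[plant.chrom] = (
            seq[: plant.start] + ins + seq[plant.start + len(ins):]
        )

    fasta = os.path.join(outdir, "genome.fa")
    with open(fasta, "w") as fh:
        for name in spec.chromosomes:
            fh.write(f">{name}\n")
            s = chrom_seqs[name]
            for i in range(0, len(s), 60):
                fh.write(s[i: i + 60] + "\n")
    for ext in (".fai",):  # stale index from a previous run would shadow the new file
        if os.path.exists(fasta + ext):
            os.remove(fasta + ext)

    gtf = os.path.join(outdir, "annotation.gtf")
    with open(gtf, "w") as fh:
        for gene in spec.genes:
            for tx_suffix, exon_indices in sorted(gene.transcript_map().items()):
                tx_id = f"{gene.gene_id}.{tx_suffix}"
                ordered = gene.tx_order(exon_indices)
                for rank, (s, e) in enumerate(ordered, 1):
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}"; '
                        f'gene_name "{gene.name}"; exon_number "{rank}";'
                    )
                    fh.write(
                        f"{gene.chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )

    paralogs_tsv = os.path.join(outdir, "paralogs.tsv")
    with open(paralogs_tsv, "w") as fh:
        for a, b in spec.paralog_pairs:
            fh.write(f"{a}\t{b}\n")

    cycle = "ACGT"
    resolved_snps: list[SnpSpec] = []
    snps_tsv = os.path.join(outdir, "snps.tsv")
    with open(snps_tsv, "w") as fh:
        for snp in spec.snps:
            ref = chrom_seqs[snp.chrom][snp.pos - 1]
            alt = snp.alt or cycle[(cycle.index(ref) + 1) % 4]
            resolved_snps.append(
                SnpSpec(snp.chrom, snp.pos, snp.snp_id, alt, snp.caf)
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{ref}\t{alt}\t{snp.caf}\n"
            )

    truth: list[TruthRow] = []
    for ev in spec.events:
        five, three = genes_by_id[ev.five_gene], genes_by_id[ev.three_gene]
        if five.strand != three.strand or five.chrom != three.chrom:
            raise ValueError(f"event {ev}: genes must share chromosome and strand")
        dbp, abp = event_breakpoints(five, three, ev.donor_exon, ev.acceptor_exon)
        truth.append(
            TruthRow(
                five_gene=ev.five_gene,
                three_gene=ev.three_gene,
                chrom=five.chrom,
                strand=five.strand,
                donor_breakpoint=dbp,
                acceptor_breakpoint=abp,
                donor_exon=ev.donor_exon,
                acceptor_exon=ev.acceptor_exon,
            )
        )
    truth_tsv = os.path.join(outdir, "truth.tsv")
    with open(truth_tsv, "w") as fh:
        fh.write(
            "five_gene_id\tthree_gene_id\tchrom\tstrand\t"
            "donor_breakpoint\tacceptor_breakpoint\n"
        )
        for t in truth:
            fh.write(
                f"{t.five_gene}\t{t.three_gene}\t{t.chrom}\t{t.strand}\t"
                f"{t.donor_breakpoint}\t{t.acceptor_breakpoint}\n"
            )

    return World(
        spec=spec, outdir=outdir, fasta=fasta, gtf=gtf,
        paralogs_tsv=paralogs_tsv, snps_tsv=snps_tsv, truth_tsv=truth_tsv,
        chrom_seqs=chrom_seqs, truth=truth, snps=resolved_snps,
    )


# --- transcript pool and read simulation -------------------------------------


def _transcript_seq(
    chrom_seqs: dict[str, str], gene: GeneSpec, exon_indices: tuple[int, ...]
) -> str:
    parts = []
    for s, e in gene.tx_order(exon_indices):
        sub = chrom_seqs[gene.chrom][s:e]
        parts.append(reverse_complement(sub) if gene.strand == "-" else sub)
    return "".join(parts)


def chimeric_transcript(
    chrom_seqs: dict[str, str],
    five: GeneSpec,
    three: GeneSpec,
    donor_idx: int,
    acceptor_idx: int,
) -> str:
    """Read-through transcript: 5' gene exons through the donor exon, then
    3' gene exons from the acceptor exon onward (transcribed orientation)."""

    def _take(gene: GeneSpec, lo: int, hi: int) -> str:
        order = gene.tx_order(tuple(range(len(gene.exons))))
        parts = []
        for s, e in order[lo:hi]:
            sub = chrom_seqs[gene.chrom][s:e]
            parts.append(reverse_complement(sub) if gene.strand == "-" else sub)
        return "".join(parts)

    return _take(five, 0, donor_idx + 1) + _take(three, acceptor_idx, 10**9)


def _apply_snps(chrom_seqs: dict[str, str], snps: list[SnpSpec]) -> dict[str, str]:
    out = dict(chrom_seqs)
    for snp in snps:
        s = out[snp.chrom]
        out[snp.chrom] = s[: snp.pos - 1] + snp.alt + s[snp.pos:]
    return out


def simulate_reads(
    world: World,
    out_prefix: str,
    read_len: int = 101,
    depth: int = 50,
    paired: bool = False,
    frag_len: int | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    alt_snps: list[SnpSpec] | None = None,
    include_normal: bool = True,
    gzip_output: bool = False,
) -> list[str]:
    """Simulate error-free (by default) reads from normal and planted chimeric
    transcripts, ``depth`` reads (or fragments when paired) per transcript,
    uniform start positions, random strand. Returns the FASTQ path(s).
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_seqs = world.chrom_seqs
    if alt_snps:
        chrom_seqs = _apply_snps(chrom_seqs, alt_snps)

    pool: list[tuple[str, str]] = []  # (name, sequence)
    if include_normal:
        for gene in world.spec.genes:
            for tx_suffix, exon_indices in sorted(gene.transcript_map().items()):
                pool.append(
                    (f"{gene.gene_id}.{tx_suffix}",
                     _transcript_seq(chrom_seqs, gene, exon_indices))
                )
    for t in world.truth:
        five, three = world.gene(t.five_gene), world.gene(t.three_gene)
        pool.append(
            (f"RT.{t.five_gene}-{t.three_gene}",
             chimeric_transcript(chrom_seqs, five, three, t.donor_exon,
                                 t.acceptor_exon))
        )

    if paired and frag_len is None:
        frag_len = 2 * read_len + 50

    def _mutate(seq: str) -> str:
        if error_rate <= 0:
            return seq
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < error_rate:
                chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
        return "".join(chars)

    mate1: list[tuple[str, str]] = []
    mate2: list[tuple[str, str]] = []
    for name, tseq in pool:
        template_len = frag_len if paired else read_len
        if len(tseq) < template_len:
            continue
        starts = rng.integers(0, len(tseq) - template_len + 1, size=depth)
        flips = rng.random(size=depth) < 0.5
        for k, (start, flip) in enumerate(zip(starts, flips)):
            frag = tseq[start: start + template_len]
            if flip:
                frag = reverse_complement(frag)
            if paired:
                mate1.append((f"{name}_f{k}/1", _mutate(frag[:read_len])))
                mate2.append(
                    (f"{name}_f{k}/2", _mutate(reverse_complement(frag[-read_len:])))
                )
            else:
                mate1.append((f"{name}_r{k}", _mutate(frag)))

    def _write(path: str, reads: list[tuple[str, str]]) -> None:
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    ext = ".fastq.gz" if gzip_output else ".fastq"
    if paired:
        p1, p2 = f"{out_prefix}_1{ext}", f"{out_prefix}_2{ext}"
        _write(p1, mate1)
        _write(p2, mate2)
        return [p1, p2]
    p = f"{out_prefix}{ext}"
    _write(p, mate1)
    return [p]


# --- canned world builders ----------------------------------------------------


def _gene(
    gene_id: str, chrom: str, strand: str, first_start: int,
    n_exons: int, exon_len: int = 120, intron_len: int = 280,
    name: str | None = None,
) -> GeneSpec:
    exons = tuple(
        (first_start + i * (exon_len + intron_len),
         first_start + i * (exon_len + intron_len) + exon_len)
        for i in range(n_exons)
    )
    return GeneSpec(gene_id, name or gene_id, chrom, strand, exons)


def figure_layout_spec(seed: int) -> FixtureSpec:
    """Two plus-strand genes with five and four exons, every donor/acceptor
    breakpoint distance within 70 kb: 5 x 4 = 20 exon combinations."""
    gene_a = _gene("GENEA", "chrT", "+", 1_000, 5)
    gene_b = _gene("GENEB", "chrT", "+", 4_000, 4)
    return FixtureSpec(
        seed=seed,
        chromosomes={"chrT": 8_000},
        genes=[gene_a, gene_b],
        events=[PlantedEvent("GENEA", "GENEB", donor_exon=1, acceptor_exon=0)],
    )


def decoy_spec(seed: int) -> FixtureSpec:
    """One victim per pre-filter, each isolated on its own chromosome, plus a
    clean two-exon gene pair that survives everything."""
    clean5 = _gene("CLN1", "chrA", "+", 1_000, 2)
    clean3 = _gene("CLN2", "chrA", "+", 2_500, 2)
    par5 = _gene("PAR1", "chrB", "+", 1_000, 1)
    par3 = _gene("PAR2", "chrB", "+", 2_000, 1)
    short5 = GeneSpec("SHRT1", "SHRT1", "chrC", "+", ((1_000, 1_019),))  # 19 bp
    short3 = _gene("SHRT2", "chrC", "+", 2_000, 1)
    iso5 = GeneSpec(
        "ISO1", "ISO1", "chrD", "+", ((1_000, 1_120), (1_500, 1_620))
    )
    iso3 = GeneSpec("ISO2", "ISO2", "chrD", "+", ((1_500, 1_620),))
    emb5 = _gene("EMB1", "chrE", "+", 1_000, 1, exon_len=100)
    emb3 = _gene("EMB2", "chrE", "+", 2_000, 1, exon_len=100)
    embhost = _gene("EMB3", "chrE", "+", 4_000, 1, exon_len=100)
    sim5 = _gene("SIM1", "chrF", "+", 1_000, 1, exon_len=100)
    sim3 = _gene("SIM2", "chrF", "+", 3_000, 1, exon_len=100)
    return FixtureSpec(
        seed=seed,
        chromosomes={f"chr{c}": 6_000 for c in "ABCDEF"},
        genes=[clean5, clean3, par5, par3, short5, short3, iso5, iso3,
               emb5, emb3, embhost, sim5, sim3],
        paralog_pairs=[("PAR1", "PAR2")],
        events=[PlantedEvent("CLN1", "CLN2", donor_exon=0, acceptor_exon=0)],
        plants=[
            # the EMB1->EMB2 junction 40-mer verbatim inside EMB3's exon
            SequencePlant("chrE", 4_030, "junction_copy",
                          ("EMB1", "EMB2", 0, 0, 20)),
            # SIM2's exon is a verbatim copy of SIM1's exon
            SequencePlant("chrF", 3_000, "exon_copy", ("SIM1", 0)),
        ],
    )


def e2e_spec(seed: int, n_events: int = 10) -> FixtureSpec:
    """``n_events`` planted read-throughs, one same-strand gene pair per
    chromosome (alternating strands), three exons per gene."""
    genes: list[GeneSpec] = []
    events: list[PlantedEvent] = []
    for i in range(n_events):
        chrom = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        # the 5' gene is upstream in transcription direction: smaller
        # coordinates on +, larger on -
        five_at, three_at = (1_000, 4_000) if strand == "+" else (4_000, 1_000)
        g5 = _gene(f"FIVE{i + 1}", chrom, strand, five_at, 3)
        g3 = _gene(f"THREE{i + 1}", chrom, strand, three_at, 3)
        genes += [g5, g3]
        events.append(
            PlantedEvent(g5.gene_id, g3.gene_id,
                         donor_exon=1 + (i % 2), acceptor_exon=i % 3)
        )
    return FixtureSpec(
        seed=seed,
        chromosomes={f"chr{i + 1}": 8_000 for i in range(n_events)},
        genes=genes,
        events=events,
    )


def snp_world_spec(seed: int) -> FixtureSpec:
    """One clean event whose donor flank window carries a common SNP (CAF 0.15)
    and whose acceptor window carries a rare one (CAF 0.05)."""
    g5 = _gene("SNPA", "chrS", "+", 1_000, 2)
    g3 = _gene("SNPB", "chrS", "+", 3_000, 2)
    donor_end = g5.exons[1][1]  # donor exon is tx index 1 on +
    acceptor_start = g3.exons[0][0]
    return FixtureSpec(
        seed=seed,
        chromosomes={"chrS": 6_000},
        genes=[g5, g3],
        events=[PlantedEvent("SNPA", "SNPB", donor_exon=1, acceptor_exon=0)],
        snps=[
            SnpSpec("chrS", donor_end - 5, "rsCOMMON", alt="", caf=0.15),
            SnpSpec("chrS", acceptor_start + 9, "rsRARE", alt="", caf=0.05),
        ],
    )
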