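"""SNP-aware expansion of the junction database.

Exact-match searching misses junctions carried on a common variant haplotype.
For every common single-nucleotide substitution falling inside one of a
junction's two flank windows, a variant junction record is added whose
sequence substitutes the alternate base at the corresponding
transcribed-orientation position. Variants inherit the parent's breakpoints
and filter status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

from intervaltree import IntervalTree

from .annotation_model import GenomeSequence
from .junction_db import JunctionRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_CAF = 0.10

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = frozenset("ACGT")


class SnpParseError(ValueError):
    pass


@dataclass(frozen=True)
class SnpRecord:
    """A common single-nucleotide substitution; one frequency per alt allele."""

    chrom: str
    pos: int  # 1-based genomic
    snp_id: str
    ref: str
    alts: tuple[str, ...]
    cafs: tuple[float, ...]

    def __post_init__(self):
        if len(self.ref) != 1 or self.ref not in _BASES:
            raise SnpParseError(f"{self.snp_id}: ref {self.ref!r} is not a single base")
        for alt, caf in zip(self.alts, self.cafs):
            if len(alt) != 1 or alt not in _BASES or alt == self.ref:
                raise SnpParseError(f"{self.snp_id}: invalid alt {alt!r}")
            if not 0.0 <= caf <= 1.0:
                raise SnpParseError(f"{self.snp_id}: CAF {caf} outside [0,1]")


def _filter_alleles(
    chrom: str, pos: int, snp_id: str, ref: str, alts, cafs, min_caf: float
) -> SnpRecord | None:
    """Keep single-base substitutions with allele frequency >= min_caf."""
    if len(ref) != 1 or ref.upper() not in _BASES:
        return None
    kept_alts, kept_cafs = [], []
    for alt, caf in zip(alts, cafs):
        alt = alt.upper()
        if len(alt) != 1 or alt not in _BASES or alt == ref.upper():
            continue
        if caf is None or caf < min_caf:
            continue
        kept_alts.append(alt)
        kept_cafs.append(float(caf))
    if not kept_alts:
        return None
    return SnpRecord(chrom, pos, snp_id, ref.upper(), tuple(kept_alts), tuple(kept_cafs))


def _load_snps_vcf(path: str, min_caf: float) -> tuple[list[SnpRecord], int]:
    import pysam

    records, dropped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = list(rec.alts or ())
            cafs: list[float | None]
            if "CAF" in rec.info:
                # dbSNP style: comma list of ref frequency then one per alt
                raw = rec.info["CAF"]
                if isinstance(raw, str):
                    raw = raw.split(",")
                vals = [None if str(v) in (".", "None") else float(v) for v in raw]
                cafs = vals[1 : 1 + len(alts)]
            elif "AF" in rec.info:
                raw = rec.info["AF"]
                if not isinstance(raw, (tuple, list)):
                    raw = (raw,)
                cafs = [float(v) for v in raw][: len(alts)]
            else:
                cafs = [None] * len(alts)
            snp = _filter_alleles(
                rec.chrom, rec.pos, rec.id or f"{rec.chrom}:{rec.pos}",
                rec.ref or "", alts, cafs, min_caf,
            )
            if snp is None:
                dropped += 1
            else:
                records.append(snp)
    return records, dropped


def _load_snps_tsv(path: str, min_caf: float) -> tuple[list[SnpRecord], int]:
    """6-column TSV: chrom, pos(1-based), id, ref, alt, caf. Multi-allelic rows
    may carry comma-separated alt and caf lists."""
    records, dropped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise SnpParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom, pos_s, snp_id, ref, alt_s, caf_s = fields
            if lineno == 1 and not pos_s.isdigit():
                continue  # header
            try:
                pos = int(pos_s)
                alts = alt_s.split(",")
                cafs = [float(c) for c in caf_s.split(",")]
                if len(cafs) == 1 and len(alts) > 1:
                    cafs = cafs * len(alts)
                if len(cafs) != len(alts):
                    raise ValueError("alt/caf arity mismatch")
            except ValueError as exc:
                raise SnpParseError(f"{path}:{lineno}: {exc}") from exc
            snp = _filter_alleles(chrom, pos, snp_id, ref, alts, cafs, min_caf)
            if snp is None:
                dropped += 1
            else:
                records.append(snp)
    return records, dropped


def load_common_snps(path: str, min_caf: float = DEFAULT_MIN_CAF) -> list[SnpRecord]:
    """Load single-nucleotide substitutions with allele frequency >= min_caf.

    Accepts VCF (INFO key CAF in dbSNP style or AF) or the 6-column TSV
    fallback. Indels, multi-nucleotide variants and below-threshold alleles
    are dropped with a tally logged at INFO level.
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        records, dropped = _load_snps_vcf(p, min_caf)
    else:
        records, dropped = _load_snps_tsv(p, min_caf)
    logger.info(
        "loaded %d common SNPs (>= %.2f allele frequency); dropped %d records",
        len(records), min_caf, dropped,
    )
    return records


def junction_genomic_intervals(
    junction: JunctionRecord,
) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
    """The two flank-length genomic windows (0-based half-open) whose
    transcribed concatenation is the junction sequence: donor window ends at
    the donor breakpoint, acceptor window starts at the acceptor breakpoint,
    both in transcription direction."""
    flank = junction.flank
    chrom = junction.chrom
    d = junction.donor_bp.position  # 1-based
    a = junction.acceptor_bp.position
    if junction.strand == "+":
        donor_win = (chrom, d - flank, d)
        accept_win = (chrom, a - 1, a - 1 + flank)
    else:
        donor_win = (chrom, d - 1, d - 1 + flank)
        accept_win = (chrom, a - flank, a)
    return donor_win, accept_win


def _transcribed_offset(junction: JunctionRecord, genomic_pos: int) -> int | None:
    """Index within the junction sequence of a 1-based genomic position, or
    None if the position falls outside both flank windows."""
    flank = junction.flank
    (_, ds, de), (_, as_, ae) = junction_genomic_intervals(junction)
    p0 = genomic_pos - 1
    if ds <= p0 < de:
        return (p0 - ds) if junction.strand == "+" else (de - 1 - p0)
    if as_ <= p0 < ae:
        off = (p0 - as_) if junction.strand == "+" else (ae - 1 - p0)
        return flank + off
    return None


def expand_with_snps(
    junctions: Iterable[JunctionRecord],
    snps: Iterable[SnpRecord],
    genome: GenomeSequence | None = None,
) -> list[JunctionRecord]:
    """Return the input junctions plus one variant record per (junction, SNP,
    qualifying alt allele) whose position falls in a flank window.

    On the minus strand the complement of the alt base is placed at the
    transcribed-orientation offset. If a genome is supplied, the SNP ref
    allele is checked against the genome base; disagreements are still emitted
    but logged. Combinations of multiple SNPs are not enumerated.
    """
    junctions = list(junctions)
    trees: dict[str, IntervalTree] = {}
    for snp in snps:
        trees.setdefault(snp.chrom, IntervalTree()).addi(
            snp.pos - 1, snp.pos, snp
        )

    out = list(junctions)
    n_variants = 0
    for junction in junctions:
        tree = trees.get(junction.chrom)
        if tree is None:
            continue
        hits: list[SnpRecord] = []
        for chrom, start, end in junction_genomic_intervals(junction):
            for iv in tree.overlap(start, end):
                hits.append(iv.data)
        for snp in sorted(set(hits), key=lambda s: (s.pos, s.snp_id)):
            idx = _transcribed_offset(junction, snp.pos)
            if idx is None:
                continue
            if genome is not None:
                genome_base = genome.fetch(snp.chrom, snp.pos - 1, snp.pos)
                if genome_base != snp.ref:
                    logger.warning(
                        "SNP %s ref %s disagrees with genome base %s at %s:%d",
                        snp.snp_id, snp.ref, genome_base, snp.chrom, snp.pos,
                    )
            for alt in snp.alts:
                base = alt if junction.strand == "+" else _COMP[alt]
                seq = junction.sequence
                if seq[idx] == base:
                    continue  # substitution would not change the sequence
                var_seq = seq[:idx] + base + seq[idx + 1:]
                out.append(
                    replace(
                        junction,
                        junction_id=f"{junction.junction_id}|{snp.snp_id}:{alt}",
                        sequence=var_seq,
                        variant_of=junction.junction_id,
                        snp_ids=junction.snp_ids + (snp.snp_id,),
                        contains_n="N" in var_seq,
                    )
                )
                n_variants += 1
    logger.info("SNP expansion added %d variant junction sequences", n_variants)
    return out
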