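"""Shared fixtures: toy genomes, canned synthetic worlds and junction helpers."""

from __future__ import annotations

import pytest

from rtchimera import fixtures as fx
from rtchimera.annotation_model import Exon, load_annotation, load_genome, load_paralogs
from rtchimera.junction_db import Breakpoint, JunctionRecord


def write_fasta(path, chrom_seqs: dict[str, str], width: int = 60) -> str:
    with open(path, "w") as fh:
        for name, seq in chrom_seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
    return str(path)


def make_junction_record(
    sequence: str,
    junction_id: str = "J1",
    chrom: str = "chrT",
    strand: str = "+",
    donor_bp: int = 200,
    acceptor_bp: int = 251,
    five_gene: str = "G5",
    three_gene: str = "G3",
    variant_of: str | None = None,
) -> JunctionRecord:
    """A minimal junction record for index/search/postfilter tests."""
    flank = len(sequence) // 2
    donor = Exon(f"{junction_id}.d", five_gene, "t", chrom,
                 donor_bp - 100, donor_bp, strand, 1)
    acceptor = Exon(f"{junction_id}.a", three_gene, "t", chrom,
                    acceptor_bp - 1, acceptor_bp + 99, strand, 1)
    return JunctionRecord(
        junction_id=junction_id,
        five_gene_id=five_gene, five_gene_name=five_gene,
        three_gene_id=three_gene, three_gene_name=three_gene,
        chrom=chrom, strand=strand,
        donor_exon=donor, acceptor_exon=acceptor,
        donor_bp=Breakpoint(chrom, donor_bp, strand),
        acceptor_bp=Breakpoint(chrom, acceptor_bp, strand),
        sequence=sequence, distance=abs(acceptor_bp - donor_bp),
        flank=flank, variant_of=variant_of,
        contains_n="N" in sequence,
    )


@pytest.fixture(scope="session")
def figure_world(tmp_path_factory):
    d = tmp_path_factory.mktemp("figure_world")
    return fx.generate_world(fx.figure_layout_spec(seed=101), str(d))


@pytest.fixture(scope="session")
def decoy_world(tmp_path_factory):
    d = tmp_path_factory.mktemp("decoy_world")
    return fx.generate_world(fx.decoy_spec(seed=202), str(d))


@pytest.fixture(scope="session")
def e2e_world(tmp_path_factory):
    d = tmp_path_factory.mktemp("e2e_world")
    return fx.generate_world(fx.e2e_spec(seed=303, n_events=10), str(d))


@pytest.fixture(scope="session")
def snp_world(tmp_path_factory):
    d = tmp_path_factory.mktemp("snp_world")
    return fx.generate_world(fx.snp_world_spec(seed=404), str(d))


@pytest.fixture(scope="session")
def loaded(figure_world):
    """(genome, annotation, paralogs) of the figure world."""
    return (
        load_genome(figure_world.fasta),
        load_annotation(figure_world.gtf),
        load_paralogs(figure_world.paralogs_tsv),
    )
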