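"""Final candidate table with breakpoint coordinates and sequences for primer
design. Coordinates in the report are 1-based (genome-browser convention);
internals stay 0-based half-open.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .annotation_model import GenomeSequence, exon_sequence
from .junction_db import JunctionRecord
from .postfilters import Candidate

REPORT_COLUMNS = [
    "five_gene_id", "five_gene_name", "three_gene_id", "three_gene_name",
    "chrom", "strand", "donor_breakpoint", "acceptor_breakpoint", "distance",
    "n_support", "supporting_reads", "junction_sequences",
    "donor_exon_seq", "acceptor_exon_seq",
]

DEFAULT_MAX_READ_IDS = 20


def _parents_by_event(junctions: Iterable[JunctionRecord]) -> dict[tuple, JunctionRecord]:
    parents: dict[tuple, JunctionRecord] = {}
    for j in junctions:
        if j.variant_of is None and j.event_key not in parents:
            parents[j.event_key] = j
    return parents


def report_rows(
    candidates: Iterable[Candidate],
    junctions: Iterable[JunctionRecord],
    genome: GenomeSequence,
    max_read_ids: int = DEFAULT_MAX_READ_IDS,
) -> list[dict]:
    """One dict per candidate, sorted by (chrom, donor, acceptor breakpoint)."""
    parents = _parents_by_event(junctions)
    rows = []
    for cand in candidates:
        parent = parents.get(cand.event_key)
        if parent is None:
            raise ValueError(f"candidate without a parent junction: {cand.event_key}")
        reads = sorted(cand.supporting_reads)
        rows.append(
            {
                "five_gene_id": parent.five_gene_id,
                "five_gene_name": parent.five_gene_name,
                "three_gene_id": parent.three_gene_id,
                "three_gene_name": parent.three_gene_name,
                "chrom": parent.chrom,
                "strand": parent.strand,
                "donor_breakpoint": parent.donor_bp.position,
                "acceptor_breakpoint": parent.acceptor_bp.position,
                "distance": parent.distance,
                "n_support": cand.n_support,
                "supporting_reads": ",".join(reads[:max_read_ids]),
                "all_supporting_reads": reads,
                "junction_sequences": ",".join(sorted(cand.matched_sequences)),
                "donor_exon_seq": exon_sequence(parent.donor_exon, genome),
                "acceptor_exon_seq": exon_sequence(parent.acceptor_exon, genome),
            }
        )
    rows.sort(
        key=lambda r: (r["chrom"], r["donor_breakpoint"], r["acceptor_breakpoint"],
                       r["five_gene_id"], r["three_gene_id"])
    )
    return rows


def write_report(
    candidates: Iterable[Candidate],
    junctions: Iterable[JunctionRecord],
    genome: GenomeSequence,
    path: str,
    max_read_ids: int = DEFAULT_MAX_READ_IDS,
    reads_sidecar_path: str | None = None,
) -> list[dict]:
    """Write the TSV report (deterministic order, no timestamps); optionally a
    sidecar TSV with the complete supporting-read lists."""
    rows = report_rows(candidates, junctions, genome, max_read_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in REPORT_COLUMNS) + "\n")
    if reads_sidecar_path is not None:
        with open(reads_sidecar_path, "w") as fh:
            fh.write("five_gene_id\tthree_gene_id\tdonor_breakpoint\t"
                     "acceptor_breakpoint\tread_id\n")
            for r in rows:
                for rid in r["all_supporting_reads"]:
                    fh.write(
                        f"{r['five_gene_id']}\t{r['three_gene_id']}\t"
                        f"{r['donor_breakpoint']}\t{r['acceptor_breakpoint']}\t{rid}\n"
                    )
    return rows


def write_bedpe(rows: Sequence[dict], path: str) -> None:
    """BEDPE export of the two breakpoint anchors per event (browser display)."""
    with open(path, "w") as fh:
        for r in rows:
            d0 = r["donor_breakpoint"] - 1
            a0 = r["acceptor_breakpoint"] - 1
            name = f"{r['five_gene_name']}-{r['three_gene_name']}"
            fh.write(
                f"{r['chrom']}\t{d0}\t{d0 + 1}\t{r['chrom']}\t{a0}\t{a0 + 1}\t"
                f"{name}\t{r['n_support']}\t{r['strand']}\t{r['strand']}\n"
            )
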