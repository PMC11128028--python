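"""Aggregation of read hits into candidate read-through events and the two
post-search filters (ambiguous-read removal, minimum supporting reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .junction_db import JunctionRecord
from .read_search import ReadHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """One read-through event with its supporting evidence."""

    event_key: tuple  # (chrom, strand, donor_bp, acceptor_bp, 5' gene, 3' gene)
    supporting_reads: frozenset[str]
    matched_sequences: frozenset[str]

    @property
    def n_support(self) -> int:
        return len(self.supporting_reads)


def collapse_to_events(
    hits: Mapping[str, ReadHit], junctions: Iterable[JunctionRecord]
) -> dict[str, dict[tuple, set[str]]]:
    """Collapse per-read junction matches to biological events.

    A parent junction, its SNP variants and both orientations share one
    event key (the breakpoint pair plus gene pair), so a read matching any of
    them supports a single event. Returns
    {read_id: {event_key: {matched 40-mers}}}. A hit naming a junction_id not
    present in the database is an error.
    """
    by_id = {j.junction_id: j for j in junctions}
    out: dict[str, dict[tuple, set[str]]] = {}
    for rid in sorted(hits):
        events: dict[tuple, set[str]] = {}
        for junction_id, _orientation in hits[rid].matches:
            record = by_id.get(junction_id)
            if record is None:
                raise ValueError(f"read hit references unknown junction {junction_id!r}")
            events.setdefault(record.event_key, set()).add(record.sequence)
        out[rid] = events
    return out


def remove_ambiguous_reads(
    event_hits: Mapping[str, Mapping[tuple, set[str]]]
) -> dict[str, dict[tuple, set[str]]]:
    """Drop reads whose event set has size != 1. Surviving reads have singleton
    event sets by construction, so this single pass is a fixed point
    (idempotent)."""
    kept = {
        rid: {k: set(v) for k, v in events.items()}
        for rid, events in event_hits.items()
        if len(events) == 1
    }
    n_ambiguous = sum(1 for events in event_hits.values() if len(events) > 1)
    if n_ambiguous:
        logger.info("discarded %d ambiguous reads supporting >1 event", n_ambiguous)
    return kept


def read_based_filter(
    event_hits: Mapping[str, Mapping[tuple, set[str]]]
) -> list[Candidate]:
    """Discard reads supporting more than one event, recompute support counts
    and drop events left with no reads."""
    support: dict[tuple, set[str]] = {}
    sequences: dict[tuple, set[str]] = {}
    for rid, events in remove_ambiguous_reads(event_hits).items():
        (event_key, seqs), = events.items()
        support.setdefault(event_key, set()).add(rid)
        sequences.setdefault(event_key, set()).update(seqs)
    return [
        Candidate(
            event_key=key,
            supporting_reads=frozenset(support[key]),
            matched_sequences=frozenset(sequences[key]),
        )
        for key in sorted(support)
    ]


def min_support_filter(
    candidates: Iterable[Candidate], min_reads: int = 1
) -> list[Candidate]:
    """Keep candidates with at least min_reads supporting reads (optional,
    min_reads=1 is the identity)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [c for c in candidates if c.n_support >= min_reads]
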