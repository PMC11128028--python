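"""Memory-bounded multi-pattern exact search of junction sequences against reads.

A read supports a junction iff it contains the junction sequence or its
reverse complement as an exact contiguous substring (fixed-string semantics: N
is not a wildcard, no mismatches, no partial overlap). Matching hashes every
fixed-length window of each read against the pattern set, so the result is a
pure function of (reads, patterns) — independent of chunking, worker count and
file order. The pattern set is split into chunks sized to a user memory
budget and the chunks are processed one by one (optionally in parallel
worker processes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from multiprocessing import get_context
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

# rough automaton/hash footprint per indexed pattern (python str + dict slot)
PATTERN_MEM_BYTES = 512


class FastqError(ValueError):
    pass


@dataclass(frozen=True)
class ReadHit:
    """All junction matches of one read; matches are (junction_id, orientation)."""

    read_id: str
    matches: frozenset[tuple[str, str]]

    @property
    def junction_ids(self) -> frozenset[str]:
        return frozenset(j for j, _ in self.matches)


@dataclass(frozen=True)
class SearchPlan:
    """Partition of the pattern set into memory-bounded chunks."""

    chunks: tuple[tuple[str, ...], ...]

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)


def plan_chunks(index, memory_budget_gb: float) -> SearchPlan:
    """Split the index's patterns into the fewest chunks whose estimated
    footprint fits the budget; chunk sizes differ by at most one."""
    if memory_budget_gb <= 0:
        raise ValueError("memory budget must be positive")
    budget_bytes = int(memory_budget_gb * 1024**3)
    if budget_bytes < PATTERN_MEM_BYTES:
        raise ValueError(
            f"memory budget {memory_budget_gb} GB is below the single-pattern minimum"
        )
    patterns = index.patterns()
    if not patterns:
        return SearchPlan(chunks=())
    n = len(patterns)
    n_chunks = max(1, -(-n * PATTERN_MEM_BYTES // budget_bytes))
    base, extra = divmod(n, n_chunks)
    chunks, at = [], 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        chunks.append(tuple(patterns[at: at + size]))
        at += size
    return SearchPlan(chunks=tuple(chunks))


def normalize_read_id(name: str, comment: str | None) -> str:
    """Canonical (fragment, mate) key so paired mates count separately.

    Recognises trailing ``/1``/``/2`` on the name and Illumina CASAVA-style
    comments (``1:N:0:...``); reads without mate information keep their name.
    """
    if name.endswith("/1") or name.endswith("/2"):
        return name
    if comment:
        tok = comment.split()[0]
        if len(tok) >= 2 and tok[0] in "12" and tok[1] == ":":
            return f"{name}/{tok[0]}"
    return name


def _is_fastq(path: str) -> bool:
    import gzip as _gzip

    opener = _gzip.open if str(path).endswith(".gz") else open
    try:
        with opener(path, "rt") as fh:
            for line in fh:
                if line.strip():
                    return line[0] == "@"
    except OSError as exc:
        raise FastqError(f"cannot read {path}: {exc}") from exc
    return False


def _scan_file_against(
    path: str, patterns_map: Mapping[str, frozenset], lengths: Sequence[int]
) -> dict[str, set]:
    hits: dict[str, set] = {}
    expect_quality = _is_fastq(path)
    try:
        fh = pysam.FastxFile(str(path))
    except OSError as exc:
        raise FastqError(f"cannot read {path}: {exc}") from exc
    with fh:
        try:
            for i, entry in enumerate(fh):
                seq = entry.sequence
                if seq is None:
                    raise FastqError(f"{path}: record {i} has no sequence")
                if expect_quality and (
                    entry.quality is None or len(entry.quality) != len(seq)
                ):
                    raise FastqError(
                        f"{path}: record {i} ({entry.name}) is malformed "
                        "(missing or truncated quality line)"
                    )
                seq = seq.upper()
                found: set | None = None
                for L in lengths:
                    for j in range(len(seq) - L + 1):
                        entries = patterns_map.get(seq[j: j + L])
                        if entries:
                            if found is None:
                                found = set()
                            found.update(entries)
                if found:
                    rid = normalize_read_id(entry.name, entry.comment)
                    hits.setdefault(rid, set()).update(found)
        except FastqError:
            raise
        except Exception as exc:
            raise FastqError(f"malformed record in {path}: {exc}") from exc
    return hits


def _scan_task(args) -> dict[str, set]:
    path, patterns_map, lengths = args
    return _scan_file_against(path, patterns_map, lengths)


def merge_hits(per_chunk_hits: Iterable[Mapping[str, set]]) -> dict[str, ReadHit]:
    """Per-read union of matches across chunks/files; deterministic keys."""
    merged: dict[str, set] = {}
    for hits in per_chunk_hits:
        for rid, matches in hits.items():
            merged.setdefault(rid, set()).update(matches)
    return {
        rid: ReadHit(read_id=rid, matches=frozenset(merged[rid]))
        for rid in sorted(merged)
    }


def scan_reads(
    fastq_paths: Sequence[str],
    index,
    plan: SearchPlan | None = None,
    threads: int = 1,
) -> dict[str, ReadHit]:
    """Search all reads in the given FASTQ/FASTA(.gz) files against the index.

    Returns {read_id: ReadHit}. The result is invariant under the chunk plan,
    the worker count and the order of input files.
    """
    if plan is None:
        plan = SearchPlan(chunks=(tuple(index.patterns()),) if len(index) else ())
    tasks = []
    for chunk in plan.chunks:
        if not chunk:
            continue
        patterns_map = {p: index.lookup(p) for p in chunk}
        lengths = sorted({len(p) for p in chunk})
        for path in fastq_paths:
            tasks.append((str(path), patterns_map, lengths))
    if not tasks:
        return {}
    if threads > 1 and len(tasks) > 1:
        ctx = get_context("fork")
        with ctx.Pool(min(threads, len(tasks))) as pool:
            results = pool.map(_scan_task, tasks)
    else:
        results = [_scan_task(t) for t in tasks]
    hits = merge_hits(results)
    logger.info(
        "read search: %d reads matched across %d chunk(s) and %d file(s)",
        len(hits), plan.n_chunks, len(fastq_paths),
    )
    return hits
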