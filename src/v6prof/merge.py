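"""Merge overlapping paired-end reads into composite amplicon reads.

Each amplicon is short enough that the forward and reverse 76-nt reads
overlap in the middle. The merger scans candidate overlap lengths from
longest to shortest, accepts the first perfect overlap inside the configured
window, and — failing that — rescans allowing exactly one mismatching
position. In the overlap, bases called identically by both reads get the sum
of their Phred scores (independent concordant observations; scores are
log-odds and therefore additive), capped so the result stays encodable. At
the single allowed mismatch the base with the higher Phred score wins and
keeps its own score.

Only perfect-overlap composites are eligible for downstream analysis;
one-mismatch merges are counted but set aside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator

from ._seq import revcomp
from .formats import SequenceRecord, read_fastq

__all__ = ["CompositeRead", "MergeStats", "merge_pair", "merge_run", "merge_files"]

QUAL_CAP_DEFAULT = 90  # keeps additive scores encodable in Phred+33


@dataclass
class CompositeRead:
    id: str
    seq: str
    qual: list[int] | None
    overlap_len: int
    overlap_mismatches: int
    status: str  # "perfect" | "one_mismatch" | "unmerged"

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, seq=self.seq, qual=self.qual)


@dataclass
class MergeStats:
    n_pairs: int = 0
    perfect: int = 0
    one_mismatch: int = 0
    unmerged: int = 0
    #: reads (counting each end separately) with >=1 base at the minimum
    #: Phred score observed anywhere in the run
    low_quality_containing: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _scan(s1: str, rc2: str, min_overlap: int, max_overlap: int, allowed_mm: int) -> tuple[int, int] | None:
    """Return (overlap_len, n_mismatches) for the longest overlap with exactly
    ``allowed_mm`` mismatches, or None. An N never matches anything."""
    hi = min(max_overlap, len(s1), len(rc2))
    for ov in range(hi, min_overlap - 1, -1):
        a = s1[len(s1) - ov:]
        b = rc2[:ov]
        mm = 0
        for x, y in zip(a, b):
            if x != y or x == "N":
                mm += 1
                if mm > allowed_mm:
                    break
        if mm == allowed_mm:
            return ov, mm
    return None


def merge_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 10,
    max_overlap: int = 50,
    qual_cap: int = QUAL_CAP_DEFAULT,
) -> CompositeRead:
    """Merge one read pair; r2 is reverse-complemented internally."""
    if len(r1) != len(r2):
        raise ValueError(f"pair {r1.id!r}: read lengths differ ({len(r1)} vs {len(r2)})")
    if r1.qual is None or r2.qual is None:
        raise ValueError(f"pair {r1.id!r}: both reads must carry quality scores")

    s1 = r1.seq
    rc2 = revcomp(r2.seq)
    q1 = r1.qual
    q2 = r2.qual[::-1]

    hit = _scan(s1, rc2, min_overlap, max_overlap, 0)
    status = "perfect"
    if hit is None:
        hit = _scan(s1, rc2, min_overlap, max_overlap, 1)
        status = "one_mismatch"
    if hit is None:
        return CompositeRead(
            id=r1.id, seq="", qual=None, overlap_len=0, overlap_mismatches=0,
            status="unmerged",
        )

    ov, mm = hit
    left = len(s1) - ov
    seq = list(s1[:left])
    qual = list(q1[:left])
    for k in range(ov):
        b1, b2 = s1[left + k], rc2[k]
        p1, p2 = q1[left + k], q2[k]
        if b1 == b2 and b1 != "N":
            seq.append(b1)
            qual.append(min(p1 + p2, qual_cap))
        else:
            # the single allowed clash: higher-Phred base wins with its own
            # score; ties keep the forward-read base
            if p1 >= p2:
                seq.append(b1)
                qual.append(p1)
            else:
                seq.append(b2)
                qual.append(p2)
    seq.extend(rc2[ov:])
    qual.extend(q2[ov:])
    return CompositeRead(
        id=r1.id, seq="".join(seq), qual=qual, overlap_len=ov,
        overlap_mismatches=mm, status=status,
    )


def merge_run(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    min_overlap: int = 10,
    max_overlap: int = 50,
    qual_cap: int = QUAL_CAP_DEFAULT,
) -> tuple[list[CompositeRead], MergeStats]:
    """Merge a whole run and tally the status classes.

    The classes partition the input: perfect + one_mismatch + unmerged equals
    the number of pairs. ``low_quality_containing`` counts single-end reads
    carrying at least one base at the minimum Phred score seen in the run
    (the run-level floor is only known at the end, hence the second pass
    over the recorded per-read minima).
    """
    stats = MergeStats()
    composites: list[CompositeRead] = []
    read_minima: list[int] = []
    for r1, r2 in pairs:
        if r1.qual:
            read_minima.append(min(r1.qual))
        if r2.qual:
            read_minima.append(min(r2.qual))
        comp = merge_pair(r1, r2, min_overlap, max_overlap, qual_cap)
        stats.n_pairs += 1
        if comp.status == "perfect":
            stats.perfect += 1
        elif comp.status == "one_mismatch":
            stats.one_mismatch += 1
        else:
            stats.unmerged += 1
        composites.append(comp)
    if read_minima:
        floor = min(read_minima)
        stats.low_quality_containing = sum(m == floor for m in read_minima)
    return composites, stats


def _paired(f1: Iterator[SequenceRecord], f2: Iterator[SequenceRecord]) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    while True:
        a = next(f1, None)
        b = next(f2, None)
        if a is None and b is None:
            return
        if a is None or b is None:
            raise ValueError("R1 and R2 files contain different numbers of reads")
        yield a, b


def merge_files(fastq1, fastq2, **kwargs) -> tuple[list[CompositeRead], MergeStats]:
    """Merge two parallel FASTQ files (pair i of file 1 with pair i of file 2)."""
    return merge_run(_paired(read_fastq(fastq1), read_fastq(fastq2)), **kwargs)
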