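"""Resolve composite reads to samples via their left/right sequence tags.

A composite read has the layout

    [left tag][left primer][V6 inter-primer region][rc(right primer)][rc(right tag)]

Tag matching is exact and full-length: the tag must be a verbatim prefix
(suffix) of the composite, immediately followed (preceded) by the primer with
at most ``max_primer_mm`` IUPAC-aware mismatches. Reads that fail are
classified into one failure class each, in a fixed priority order, so the
classes always partition the rejects.

Variable tag lengths mean a tag can collide with the N-1 synthesis
truncation of a longer tag (an oligo missing its 5'-terminal base). Such
matches are resolved but flagged ``n1_ambiguous``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from ._seq import iupac_mismatches, revcomp
from .formats import SampleSheet, SequenceRecord, TagEntry, TagTable
from .merge import CompositeRead

__all__ = [
    "PrimerPair",
    "DemuxRecord",
    "FailureClass",
    "DemuxStats",
    "TagSetReport",
    "demux_read",
    "demux_run",
    "validate_tag_set",
    "primer_coverage",
]

#: conserved segments flanking the V6 region, 1-based E. coli 16S coordinates
LEFT_PRIMER_DEFAULT = "CAACGCGARGAACCTTACC"  # 967-985
RIGHT_PRIMER_DEFAULT = "ACAACACGAGCTGACGAC"  # 1078-1061 (reverse strand)


@dataclass(frozen=True)
class PrimerPair:
    left: str = LEFT_PRIMER_DEFAULT
    right: str = RIGHT_PRIMER_DEFAULT

    def __post_init__(self) -> None:
        from .formats import FormatError
        from Bio.Data.IUPACData import ambiguous_dna_values

        for name, seq in (("left", self.left), ("right", self.right)):
            if not set(seq) <= set(ambiguous_dna_values):
                raise FormatError(f"{name} primer contains non-IUPAC letters: {seq!r}")


class FailureClass(Enum):
    """Why a composite read could not be assigned to a sample.

    Declaration order is the classification priority: a read matching
    several descriptions is assigned the first.
    """

    tag_n1_truncated = "tag_n1_truncated"
    tag_absent = "tag_absent"
    extra_5prime_bases = "extra_5prime_bases"
    tag_mismatch = "tag_mismatch"
    primer_fail = "primer_fail"
    pair_not_in_sheet = "pair_not_in_sheet"


@dataclass
class DemuxRecord:
    read_id: str
    left_tag_name: str
    right_tag_name: str
    sample_id: str
    #: V6 region between the primers, forward orientation
    interprimer_seq: str
    interprimer_qual: list[int] | None
    left_primer_mm: int
    right_primer_mm: int
    #: observed primer regions, both given in primer orientation
    left_primer_obs: str = ""
    right_primer_obs: str = ""
    n1_ambiguous: bool = False


@dataclass
class DemuxStats:
    n_input: int = 0
    n_assigned: int = 0
    failures: Counter = field(default_factory=Counter)
    per_sample: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_assigned": self.n_assigned,
            "failures": {k.value if isinstance(k, FailureClass) else k: v
                         for k, v in self.failures.items()},
            "per_sample": dict(self.per_sample),
        }


def _n1_collision_sources(tags: Sequence[TagEntry]) -> dict[str, list[str]]:
    """tag seq -> longer same-side tag seqs whose N-1 truncation equals it."""
    seqs = {t.seq for t in tags}
    out: dict[str, list[str]] = {}
    for t in tags:
        trunc = t.seq[1:]
        if trunc in seqs:
            out.setdefault(trunc, []).append(t.seq)
    return out


def _resolve_side(
    seq: str,
    tags: Sequence[TagEntry],
    primer: str,
    max_mm: int,
) -> tuple[TagEntry, int] | FailureClass:
    """Resolve the 5' tag+primer of ``seq`` (already in primer orientation).

    Returns (tag, primer_mismatches) on success, else the failure class for
    this side alone.
    """
    plen = len(primer)
    candidates: list[tuple[int, int, TagEntry]] = []
    for tag in tags:
        t = len(tag.seq)
        if seq[:t] != tag.seq or len(seq) < t + plen:
            continue
        mm = iupac_mismatches(primer, seq[t:t + plen])
        if mm <= max_mm:
            candidates.append((mm, -t, tag))
    if candidates:
        mm, neg_t, tag = min(candidates, key=lambda c: (c[0], c[1]))
        return tag, mm

    # failure diagnosis for this side
    # N-1 truncated tag: a known tag minus its 5' base, not itself a valid tag
    seqs = {t.seq for t in tags}
    for tag in tags:
        trunc = tag.seq[1:]
        if trunc in seqs:
            continue  # would have resolved above (as the shorter valid tag)
        t = len(trunc)
        if seq[:t] == trunc and len(seq) >= t + plen:
            if iupac_mismatches(primer, seq[t:t + plen]) <= max_mm:
                return FailureClass.tag_n1_truncated

    # locate the primer at small offsets to separate the remaining classes
    best_off: int | None = None
    for off in range(0, 9):
        if len(seq) < off + plen:
            break
        if iupac_mismatches(primer, seq[off:off + plen]) <= max_mm:
            best_off = off
            break
    if best_off is None:
        return FailureClass.primer_fail
    if best_off == 0:
        return FailureClass.tag_absent
    prefix = seq[:best_off]
    # extra bases stacked 5' of an otherwise valid tag
    for tag in tags:
        if prefix.endswith(tag.seq) and len(prefix) > len(tag.seq):
            return FailureClass.extra_5prime_bases
    if best_off > max(len(t.seq) for t in tags):
        return FailureClass.extra_5prime_bases
    return FailureClass.tag_mismatch


def demux_read(
    composite: CompositeRead,
    tags: TagTable,
    primers: PrimerPair,
    sheet: SampleSheet,
    max_primer_mm: int = 3,
) -> DemuxRecord | FailureClass:
    """Assign one perfect-overlap composite read to a sample, or classify
    the failure. Right-side resolution works on the reverse complement of
    the composite, which puts the right tag+primer in 5'->3' primer
    orientation — the two sides are then symmetric."""
    seq = composite.seq
    left = _resolve_side(seq, tags.side("left"), primers.left, max_primer_mm)
    right = _resolve_side(revcomp(seq), tags.side("right"), primers.right, max_primer_mm)

    failures = [r for r in (left, right) if isinstance(r, FailureClass)]
    if failures:
        return min(failures, key=lambda f: list(FailureClass).index(f))

    ltag, lmm = left
    rtag, rmm = right
    sample = sheet.sample_for(ltag.name, rtag.name)
    if sample is None:
        return FailureClass.pair_not_in_sheet

    lstart = len(ltag.seq)
    istart = lstart + len(primers.left)
    iend = len(seq) - len(rtag.seq) - len(primers.right)
    n1_sources = _n1_collision_sources(tags.side("left")) | _n1_collision_sources(tags.side("right"))
    qual = composite.qual[istart:iend] if composite.qual is not None else None
    return DemuxRecord(
        read_id=composite.id,
        left_tag_name=ltag.name,
        right_tag_name=rtag.name,
        sample_id=sample,
        interprimer_seq=seq[istart:iend],
        interprimer_qual=qual,
        left_primer_mm=lmm,
        right_primer_mm=rmm,
        left_primer_obs=seq[lstart:istart],
        right_primer_obs=revcomp(seq[iend:len(seq) - len(rtag.seq)]),
        n1_ambiguous=(ltag.seq in n1_sources) or (rtag.seq in n1_sources),
    )


def demux_run(
    composites: Iterable[CompositeRead],
    tags: TagTable,
    primers: PrimerPair,
    sheet: SampleSheet,
    max_primer_mm: int = 3,
    keep_n1_ambiguous: bool = True,
) -> tuple[list[DemuxRecord], DemuxStats]:
    """Demultiplex a run of perfect-overlap composites.

    Assigned records plus the failure histogram partition the input.
    """
    sheet.validate_against(tags)
    stats = DemuxStats()
    records: list[DemuxRecord] = []
    for comp in composites:
        stats.n_input += 1
        result = demux_read(comp, tags, primers, sheet, max_primer_mm)
        if isinstance(result, FailureClass):
            stats.failures[result] += 1
        elif result.n1_ambiguous and not keep_n1_ambiguous:
            stats.failures[FailureClass.tag_n1_truncated] += 1
        else:
            stats.n_assigned += 1
            stats.per_sample[result.sample_id] += 1
            records.append(result)
    return records, stats


# ---------------------------------------------------------------------------
# tag-set validation


@dataclass
class TagSetReport:
    side: str
    #: tag sequences equal to a longer same-side tag minus its 5' base
    n1_collisions: list[str]
    #: base -> positions (1-4) at which it occurs across the tag set
    base_balance: dict[str, list[int]]
    length_range: tuple[int, int]

    @property
    def balanced_first_four(self) -> bool:
        """All four nucleotides represented at each of the first 4 positions
        (the base-caller normalizes intensities on the first cycles)."""
        return all(
            pos in self.base_balance.get(b, []) for b in "ACGT" for pos in (1, 2, 3, 4)
        )


def validate_tag_set(tags: TagTable, side: str) -> TagSetReport:
    entries = tags.side(side)
    if not entries:
        raise ValueError(f"no tags on side {side!r}")
    collisions = sorted(_n1_collision_sources(entries))
    balance: dict[str, list[int]] = {b: [] for b in "ACGT"}
    for pos in range(1, 5):
        for e in entries:
            if len(e.seq) >= pos:
                b = e.seq[pos - 1]
                if pos not in balance[b]:
                    balance[b].append(pos)
    lengths = [len(e.seq) for e in entries]
    return TagSetReport(
        side=side,
        n1_collisions=collisions,
        base_balance=balance,
        length_range=(min(lengths), max(lengths)),
    )


# ---------------------------------------------------------------------------
# primer coverage scanning


def _anchored_match(ref: str, primer: str, anchor_len: int, max_mm: int) -> bool:
    """Any placement with a perfect 3' anchor and <= max_mm elsewhere?"""
    plen = len(primer)
    body, anchor = primer[:-anchor_len], primer[-anchor_len:]
    for start in range(0, len(ref) - plen + 1):
        window = ref[start:start + plen]
        if iupac_mismatches(anchor, window[plen - anchor_len:]) != 0:
            continue
        if iupac_mismatches(body, window[:plen - anchor_len]) <= max_mm:
            return True
    return False


def primer_coverage(
    references: Iterable[SequenceRecord],
    primer: str,
    anchor_len: int = 5,
    max_mm: int = 2,
    as_revcomp: bool = False,
) -> tuple[dict[str, bool], tuple[int, int]]:
    """Scan references for an anchored approximate primer site.

    A reference matches if some placement has zero mismatches at the
    ``anchor_len`` 3'-terminal primer bases and at most ``max_mm``
    IUPAC-aware mismatches in the remainder. Set ``as_revcomp`` for the
    right primer, which anneals to the forward reference strand as its
    reverse complement. Returns per-reference booleans and the
    (matched, total) summary.
    """
    if anchor_len > len(primer):
        raise ValueError("anchor_len exceeds primer length")
    per_ref: dict[str, bool] = {}
    for rec in references:
        ref = rec.seq if not as_revcomp else revcomp(rec.seq)
        per_ref[rec.id] = _anchored_match(ref, primer, anchor_len, max_mm)
    matched = sum(per_ref.values())
    return per_ref, (matched, len(per_ref))
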