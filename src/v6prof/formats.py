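"""Record types and readers/writers for the external formats the pipeline touches.

FASTQ is fixed to the Sanger Phred+33 encoding; the historical Phred+64
dialect is available behind an explicit ``offset=64`` argument and is never
auto-detected (silent auto-detection is a classic source of corrupted
qualities).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

SANGER_OFFSET = 33

__all__ = [
    "SequenceRecord",
    "TagEntry",
    "TagTable",
    "SampleSheet",
    "CountTable",
    "Blast6Hit",
    "FormatError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_blast6",
    "default_tag_table",
]


class FormatError(ValueError):
    """A malformed record in an external file."""


@dataclass
class SequenceRecord:
    """One named nucleotide sequence with optional per-base Phred scores."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: qual length {len(self.qual)} "
                f"!= seq length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def decode_qual(qual_str: str, offset: int = SANGER_OFFSET) -> list[int]:
    scores = [ord(c) - offset for c in qual_str]
    if any(q < 0 for q in scores):
        raise FormatError(f"quality character below offset {offset}: {qual_str!r}")
    return scores


def encode_qual(scores: Sequence[int], offset: int = SANGER_OFFSET) -> str:
    out = []
    for q in scores:
        if q < 0:
            raise FormatError(f"negative Phred score: {q}")
        out.append(chr(q + offset))
    return "".join(out)


def read_fastq(path, offset: int = SANGER_OFFSET) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line-per-record FASTQ file.

    Malformed records raise :class:`FormatError` naming the (0-based)
    record index.
    """
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"FASTQ record {i}: {exc}") from exc
            if len(seq) != len(qual):
                raise FormatError(
                    f"FASTQ record {i}: seq length {len(seq)} != qual length {len(qual)}"
                )
            yield SequenceRecord(
                id=title.split()[0], seq=seq.upper(), qual=decode_qual(qual, offset)
            )
            i += 1


def write_fastq(records: Iterable[SequenceRecord], path, offset: int = SANGER_OFFSET) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.qual is None:
                raise FormatError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{encode_qual(rec.qual, offset)}\n")


def read_fasta(path) -> Iterator[SequenceRecord]:
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            yield SequenceRecord(id=title.split()[0], seq=seq.upper())


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write FASTA; qualities, when present, are dropped."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# tag table and sample sheet


@dataclass(frozen=True)
class TagEntry:
    """One sample-coding sequence tag attached to the 5' end of a PCR primer."""

    name: str
    side: str  # "left" or "right"
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if self.side not in ("left", "right"):
            raise FormatError(f"tag {self.name!r}: side must be left/right, got {self.side!r}")
        if not 3 <= len(self.seq) <= 6:
            raise FormatError(f"tag {self.name!r}: length {len(self.seq)} outside [3, 6]")
        if not set(self.seq) <= set("ACGT"):
            raise FormatError(f"tag {self.name!r}: non-ACGT character in {self.seq!r}")


class TagTable:
    """The set of left- and right-side sequence tags used on a run."""

    def __init__(self, entries: Iterable[TagEntry]):
        self.entries = list(entries)
        names = [(e.side, e.name) for e in self.entries]
        if len(set(names)) != len(names):
            raise FormatError("duplicate (side, name) in tag table")

    def side(self, side: str) -> list[TagEntry]:
        return [e for e in self.entries if e.side == side]

    def by_name(self, side: str, name: str) -> TagEntry:
        for e in self.entries:
            if e.side == side and e.name == name:
                return e
        raise KeyError(f"no {side} tag named {name!r}")

    def sequences(self, side: str) -> set[str]:
        return {e.seq for e in self.side(side)}

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("name\tside\tseq\n")
            for e in self.entries:
                fh.write(f"{e.name}\t{e.side}\t{e.seq}\n")

    @classmethod
    def from_tsv(cls, path) -> "TagTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            TagEntry(name=r["name"], side=r["side"], seq=r["seq"])
            for _, r in df.iterrows()
        )


#: the published 18 left / 16 right variable-length tag set
_DEFAULT_TAGS: list[tuple[str, str, str]] = [
    # (left tag, left name) / (right tag, right name), row-wise
    ("catgcg", "0-v6L", "left"), ("cgcatg", "0-v6R", "right"),
    ("gcagt", "1-v6L", "left"), ("actgc", "1-v6R", "right"),
    ("tagct", "2-v6L", "left"), ("agcta", "2-v6R", "right"),
    ("gactgt", "3-v6L", "left"), ("acagtc", "3-v6R", "right"),
    ("cgtcga", "4-v6L", "left"), ("tcgacg", "4-v6R", "right"),
    ("gtcgc", "5-v6L", "left"), ("gcgac", "5-v6R", "right"),
    ("acgta", "6-v6L", "left"), ("tacgt", "6-v6R", "right"),
    ("cactac", "7-v6L", "left"), ("gtagtg", "7-v6R", "right"),
    ("tgac", "8-v6L", "left"), ("gtca", "8-v6R", "right"),
    ("agta", "9-v6L", "left"), ("tact", "9-v6R", "right"),
    ("atga", "10-v6L", "left"), ("tcat", "10-v6R", "right"),
    ("tgca", "11-v6L", "left"), ("tgca", "11-v6R", "right"),
    ("act", "12-v6L", "left"), ("agt", "12-v6R", "right"),
    ("tcg", "13-v6L", "left"), ("cga", "13-v6R", "right"),
    ("gta", "14-v6L", "left"), ("tac", "14-v6R", "right"),
    ("cta", "15-v6L", "left"), ("tag", "15-v6R", "right"),
    ("tga", "16-v6L", "left"),
    ("gcta", "17-v6L", "left"),
]


def default_tag_table() -> TagTable:
    """The published tag set (lowercase in print, uppercased internally)."""
    return TagTable(TagEntry(name=n, side=s, seq=t) for t, n, s in _DEFAULT_TAGS)


@dataclass
class SampleSheet:
    """Rows of (left tag name, right tag name, sample id).

    The combinatorial coding: a sample is identified by the *pair* of tags,
    so a handful of primers covers hundreds of samples.
    """

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(l, r) for l, r, _ in self.rows]
        if len(set(pairs)) != len(pairs):
            raise FormatError("duplicate (left_tag, right_tag) pair in sample sheet")
        ids = [s for _, _, s in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in sample sheet")

    def validate_against(self, tags: TagTable) -> None:
        left = {e.name for e in tags.side("left")}
        right = {e.name for e in tags.side("right")}
        for l, r, sample in self.rows:
            if l not in left:
                raise FormatError(f"sample {sample!r}: unknown left tag {l!r}")
            if r not in right:
                raise FormatError(f"sample {sample!r}: unknown right tag {r!r}")

    def sample_for(self, left_name: str, right_name: str) -> str | None:
        for l, r, sample in self.rows:
            if l == left_name and r == right_name:
                return sample
        return None

    @property
    def sample_ids(self) -> list[str]:
        return [s for _, _, s in self.rows]

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("left_tag\tright_tag\tsample_id\n")
            for l, r, s in self.rows:
                fh.write(f"{l}\t{r}\t{s}\n")

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([(r["left_tag"], r["right_tag"], r["sample_id"]) for _, r in df.iterrows()])


# ---------------------------------------------------------------------------
# count table


class CountTable:
    """Samples x features matrix of non-negative integer read counts."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise FormatError("CountTable labels must be unique")
        if (df.to_numpy() < 0).any():
            raise FormatError("CountTable entries must be non-negative")
        self.df = df.astype(int)

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, int]], features: Sequence[str] | None = None) -> "CountTable":
        df = pd.DataFrame.from_dict(counts, orient="index").fillna(0)
        if features is not None:
            df = df.reindex(columns=list(features), fill_value=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("sample_id\t" + "\t".join(map(str, self.df.columns)) + "\n")
            for sample, row in self.df.iterrows():
                fh.write(str(sample) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6 style)

_BLAST6_COLS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches", "gap_opens",
    "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass
class Blast6Hit:
    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_annotation: str = ""

    def query_coverage(self, query_length: int) -> float:
        """Percent of the query covered by this alignment."""
        return 100.0 * (abs(self.q_end - self.q_start) + 1) / query_length


def read_blast6(path) -> list[Blast6Hit]:
    """Parse a tab-separated BLAST hit table (12 standard columns, with an
    optional 13th free-text subject annotation)."""
    hits: list[Blast6Hit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise FormatError(
                    f"line {lineno}: expected 12 or 13 tab-separated columns, got {len(parts)}"
                )
            try:
                hit = Blast6Hit(
                    query=parts[0],
                    subject=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    subject_annotation=parts[12] if len(parts) == 13 else "",
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits
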