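"""Rule-based taxonomic assignment of OTU seed sequences from BLAST hits.

General-purpose classifiers are built for near-full-length 16S sequences
and perform poorly on a 72-92 nt V6 fragment, so assignment here is a
small, explicit rule set over a BLAST hit table:

* **species** — some hit has 100% identity and 100% query coverage, and no
  hit to a *different* species comes within ``margin_identity`` percentage
  points of 100;
* **genus** — top identity is at least 95% and every hit within the margin
  of the top shares one genus;
* otherwise the assignment is the lowest taxonomic level shared by the
  lineages of all hits within the margin of the top (an LCA over the
  near-best hits).

Lineages come from a user-supplied subject -> lineage table; nothing is
queried live.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .formats import Blast6Hit

__all__ = [
    "Lineage",
    "TaxonomicAssignment",
    "read_lineage_tsv",
    "assign",
]

#: ranks ordered from broadest to most specific
RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]


@dataclass(frozen=True)
class Lineage:
    """Named levels from kingdom down to species; missing tail levels allowed."""

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.levels or len(self.levels) > len(RANKS):
            raise ValueError(f"lineage must have 1-{len(RANKS)} levels")
        if any(not lv for lv in self.levels):
            raise ValueError("empty level name in lineage")

    @property
    def species(self) -> str | None:
        return self.levels[6] if len(self.levels) > 6 else None

    @property
    def genus(self) -> str | None:
        return self.levels[5] if len(self.levels) > 5 else None

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        return cls(tuple(part.strip() for part in text.split(";")))


def read_lineage_tsv(path) -> dict[str, Lineage]:
    """subject id -> semicolon-separated lineage, two tab-separated columns."""
    df = pd.read_csv(path, sep="\t", header=None, names=["subject", "lineage"], dtype=str)
    return {r["subject"]: Lineage.from_string(r["lineage"]) for _, r in df.iterrows()}


@dataclass
class TaxonomicAssignment:
    otu_id: str
    rank: str  # "species" | "genus" | a broader rank name | "unassigned"
    name: str
    evidence: list[Blast6Hit] = field(default_factory=list)
    ambiguous: bool = False


def _lca(lineages: Sequence[Lineage]) -> tuple[str, str]:
    """(rank name, taxon name) of the lowest level shared by all lineages."""
    depth = min(len(ln.levels) for ln in lineages)
    best: tuple[str, str] | None = None
    for i in range(depth):
        names = {ln.levels[i] for ln in lineages}
        if len(names) == 1:
            best = (RANKS[i], names.pop())
        else:
            break
    return best if best is not None else ("unassigned", "")


def assign(
    otu_id: str,
    hits: Sequence[Blast6Hit],
    lineages: Mapping[str, Lineage],
    query_length: int,
    margin_identity: float = 1.0,
    exclude_environmental: bool = False,
) -> TaxonomicAssignment:
    """Classify one OTU seed from its BLAST hits.

    ``margin_identity`` is the identity window (percentage points below the
    top hit) inside which competing hits count as support or conflict.
    ``exclude_environmental`` drops subjects whose annotation contains
    'uncultured' or 'environmental' before applying the rules, mirroring
    the usual database restriction for reference-quality sequences.
    """
    usable = []
    for h in hits:
        if h.subject not in lineages:
            raise ValueError(f"hit subject {h.subject!r} has no lineage")
        if exclude_environmental:
            text = (h.subject_annotation or "").lower()
            if "uncultured" in text or "environmental" in text:
                continue
        usable.append(h)
    # deterministic regardless of input row order
    usable.sort(key=lambda h: (-h.pct_identity, -h.bitscore, h.subject))

    if not usable:
        return TaxonomicAssignment(otu_id=otu_id, rank="unassigned", name="", ambiguous=True)

    top = usable[0].pct_identity
    within = [h for h in usable if h.pct_identity >= top - margin_identity]

    perfect = [
        h for h in usable
        if h.pct_identity == 100.0 and h.query_coverage(query_length) >= 100.0
        and lineages[h.subject].species is not None
    ]
    if perfect:
        sp = lineages[perfect[0].subject].species
        rivals = [
            h for h in usable
            if h.pct_identity >= 100.0 - margin_identity
            and lineages[h.subject].species != sp
        ]
        if not rivals:
            return TaxonomicAssignment(otu_id=otu_id, rank="species", name=sp, evidence=perfect)

    if top >= 95.0:
        genera = {lineages[h.subject].genus for h in within}
        if len(genera) == 1 and None not in genera:
            return TaxonomicAssignment(
                otu_id=otu_id, rank="genus", name=genera.pop(), evidence=within
            )

    rank, name = _lca([lineages[h.subject] for h in within])
    return TaxonomicAssignment(
        otu_id=otu_id,
        rank=rank,
        name=name,
        evidence=within,
        ambiguous=(rank == "unassigned"),
    )
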