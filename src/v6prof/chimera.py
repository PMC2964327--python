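"""Threshold and summarize externally computed chimera scores.

Chimera detection itself happens outside the pipeline (e.g. UCHIME); this
module consumes its per-ISU scores, applies a score cutoff, and reports how
much of the dataset — at ISU and at read level — the flagged sequences
represent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .derep_cluster import ISU

__all__ = ["ChimeraRecord", "ChimeraSummary", "read_score_table", "apply_cutoff"]


@dataclass
class ChimeraRecord:
    isu_id: int
    score: float
    flagged_default: bool = False

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("chimera score must be non-negative")


@dataclass
class ChimeraSummary:
    n_isus_flagged: int
    n_reads_flagged: int
    pct_isus: float
    pct_reads: float
    flagged_isu_ids: list[int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def read_score_table(
    path, id_col: int = 1, score_col: int = 0, flag_col: int | None = None,
    id_prefix: str = "isu_",
) -> list[ChimeraRecord]:
    """Parse a UCHIME-style tab-separated score table.

    Default column layout is the classic uchimeout format (score first,
    query id second); indices are configurable for other layouts. ISU ids
    are parsed from ``<id_prefix><n>`` query names or plain integers.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                raw_id = parts[id_col]
                if raw_id.startswith(id_prefix):
                    raw_id = raw_id[len(id_prefix):]
                raw_id = raw_id.split("_")[0]  # tolerate isu_<n>_count_<c> names
                records.append(
                    ChimeraRecord(
                        isu_id=int(raw_id),
                        score=float(parts[score_col]),
                        flagged_default=(
                            parts[flag_col].strip().upper() == "Y"
                            if flag_col is not None else False
                        ),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"chimera table line {lineno}: {exc}") from exc
    return records


def apply_cutoff(
    records: Iterable[ChimeraRecord],
    isus: Sequence[ISU],
    cutoff: float | None = 10.0,
    total_reads: int | None = None,
) -> ChimeraSummary:
    """Flag ISUs with score >= cutoff (or the detector's own flag when
    ``cutoff`` is None) and summarize the flagged fraction of the dataset.

    Percentages are of the demultiplexed totals: all ISUs, and
    ``total_reads`` (defaults to the sum of ISU counts).
    """
    by_id = {isu.isu_id: isu for isu in isus}
    flagged: list[int] = []
    for rec in records:
        if rec.isu_id not in by_id:
            raise KeyError(f"chimera score references unknown ISU {rec.isu_id}")
        hit = rec.flagged_default if cutoff is None else rec.score >= cutoff
        if hit:
            flagged.append(rec.isu_id)
    flagged = sorted(set(flagged))
    n_reads = sum(by_id[i].total_count for i in flagged)
    denom_reads = total_reads if total_reads is not None else sum(i.total_count for i in isus)
    return ChimeraSummary(
        n_isus_flagged=len(flagged),
        n_reads_flagged=n_reads,
        pct_isus=100.0 * len(flagged) / len(isus) if isus else 0.0,
        pct_reads=100.0 * n_reads / denom_reads if denom_reads else 0.0,
        flagged_isu_ids=flagged,
    )
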