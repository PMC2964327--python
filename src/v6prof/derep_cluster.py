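"""Dereplicate inter-primer sequences into ISUs and cluster ISUs into OTUs.

An ISU (individual sequence unit) is the set of reads whose inter-primer
sequences are exactly identical. ISUs are ranked by total abundance (ties
broken lexicographically by sequence) and clustered greedily: scanning from
the most to the least abundant, each ISU joins the existing seed of highest
identity at or above the threshold, or founds a new OTU. Ordering by
abundance makes the seeds the most-observed — and therefore most likely
error-free — sequences.

Identity between two sequences is 1 - d/max(len), where d is the
Levenshtein (edit) distance; at the default 0.95 threshold a 76-mer may
differ from its seed by up to 3 edits.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

__all__ = [
    "ISU",
    "OTU",
    "DistanceMatrix",
    "dereplicate",
    "levenshtein",
    "identity",
    "cluster_otus",
    "levenshtein_matrix",
    "nj_tree",
    "otu_count_table",
]


@dataclass
class ISU:
    isu_id: int
    seq: str
    total_count: int
    per_sample_counts: dict[str, int]

    def __post_init__(self) -> None:
        assert sum(self.per_sample_counts.values()) == self.total_count


@dataclass
class OTU:
    otu_id: int
    seed_isu_id: int
    #: (isu_id, edit distance to seed, identity)
    members: list[tuple[int, int, float]]
    total_count: int
    per_sample_counts: dict[str, int]


def dereplicate(
    reads: Iterable[tuple[str, str]],
) -> tuple[list[ISU], dict[str, int]]:
    """Collapse (sample_id, inter-primer seq) observations into ISUs.

    Returns the abundance-ordered ISU list and a seq -> isu_id index.
    """
    per_seq: dict[str, Counter] = defaultdict(Counter)
    for sample, seq in reads:
        per_seq[seq][sample] += 1
    ordered = sorted(per_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    isus = [
        ISU(
            isu_id=i,
            seq=seq,
            total_count=sum(counts.values()),
            per_sample_counts=dict(counts),
        )
        for i, (seq, counts) in enumerate(ordered)
    ]
    return isus, {isu.seq: isu.isu_id for isu in isus}


def levenshtein(a: str, b: str) -> int:
    """Minimal number of substitutions, insertions or deletions."""
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def identity(a: str, b: str) -> float:
    """Pairwise identity: 1 - edit distance / max length."""
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def cluster_otus(isus: Sequence[ISU], threshold: float = 0.95) -> list[OTU]:
    """Abundance-ordered greedy clustering of ISUs around seed sequences.

    Each ISU, visited in id order, joins the seed with the highest identity
    >= threshold (ties -> lower otu_id) or becomes a new seed. Assignment is
    best-hit, not first-hit, so inserting a new seed never reshuffles
    earlier members.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    for i, isu in enumerate(isus):
        if isu.isu_id != i:
            raise ValueError("ISUs must be supplied in id (abundance) order")

    otus: list[OTU] = []
    for isu in isus:
        best: tuple[float, int] | None = None  # (identity, otu_id)
        for otu in otus:
            seed_seq = isus[otu.seed_isu_id].seq
            ident = identity(isu.seq, seed_seq)
            if ident >= threshold and (best is None or ident > best[0]):
                best = (ident, otu.otu_id)
        if best is None:
            otus.append(
                OTU(
                    otu_id=len(otus),
                    seed_isu_id=isu.isu_id,
                    members=[(isu.isu_id, 0, 1.0)],
                    total_count=isu.total_count,
                    per_sample_counts=dict(isu.per_sample_counts),
                )
            )
        else:
            ident, oid = best
            otu = otus[oid]
            dist = levenshtein(isu.seq, isus[otu.seed_isu_id].seq)
            otu.members.append((isu.isu_id, dist, ident))
            otu.total_count += isu.total_count
            for s, c in isu.per_sample_counts.items():
                otu.per_sample_counts[s] = otu.per_sample_counts.get(s, 0) + c
    return otus


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T) or np.diag(self.data).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def levenshtein_matrix(
    isus: Sequence[ISU],
    sample_totals: Mapping[str, int],
    min_sample_freq: float = 0.01,
) -> DistanceMatrix:
    """All-pairs edit distances over the ISUs reaching ``min_sample_freq``
    (count / sample total) in at least one sample."""
    if not 0.0 < min_sample_freq < 1.0:
        raise ValueError("min_sample_freq must be in (0, 1)")
    subset = [
        isu
        for isu in isus
        if any(
            sample_totals.get(s, 0) > 0 and c / sample_totals[s] >= min_sample_freq
            for s, c in isu.per_sample_counts.items()
        )
    ]
    if not subset:
        raise ValueError("no ISU reaches the frequency threshold in any sample")
    n = len(subset)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(subset[i].seq, subset[j].seq)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(ids=[f"isu_{isu.isu_id}" for isu in subset], data=data)


def nj_tree(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbour joining; returns an unrooted Newick string with
    negative branch lengths clamped to zero."""
    if len(dm.ids) < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(dm.data, ids=dm.ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def otu_count_table(otus: Sequence[OTU], samples: Sequence[str]):
    """Sample x OTU CountTable (columns ``otu_<id>``)."""
    from .formats import CountTable
    import pandas as pd

    df = pd.DataFrame(
        {f"otu_{o.otu_id}": [o.per_sample_counts.get(s, 0) for s in samples] for o in otus},
        index=list(samples),
    )
    df.index.name = "sample_id"
    return CountTable(df)
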