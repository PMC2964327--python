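"""Synthetic paired-end amplicon runs with a ground-truth manifest.

The generator emulates the stages a real V6 amplicon passes through:

* a per-sample community of reference V6 templates with fixed relative
  abundances, sampled multinomially per read;
* amplicon assembly — left tag + realized left primer + template +
  rc(right primer) + rc(right tag), with the primer's degenerate R position
  realized as A or G once per reference template (so the split at that
  position reflects template composition, not error);
* PCR substitution errors accumulated along a lineage of amplification
  cycles: a random final molecule descends through ``pcr_cycles``
  replications, each of which can substitute any base independently, so the
  per-read substitution count is Binomial(L x cycles, rate) — errors born
  in early cycles are inherited by many descendants, late ones by few,
  giving the observed mixture of per-read error loads;
* PCR chimeras spliced from two templates of the same sample at a uniform
  breakpoint;
* tag N-1 synthesis truncation (the oligo missing its 5'-terminal base) at a
  configurable per-tag rate;
* paired-end sequencing: R1 is the first ``read_length`` bases of the
  amplicon, R2 the reverse complement of the last ``read_length``; per-base
  Phred scores decay linearly with distance from the sequencing primer with
  Gaussian jitter, and a base is miscalled with probability 10^(-Q/10).

Everything is driven by one seeded generator; the same seed reproduces the
run byte for byte. The manifest records, per read pair, every event the
generator injected, so downstream stages can be audited read by read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .demux import PrimerPair
from .formats import SampleSheet, SequenceRecord, TagTable, default_tag_table

__all__ = [
    "CommunityProfile",
    "SimConfig",
    "TruthManifest",
    "ReadTruth",
    "simulate_run",
    "default_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CommunityProfile:
    """Reference V6 templates and their relative abundances in one sample."""

    members: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community must have at least one member")
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        for seq, a in self.members:
            if a <= 0:
                raise ValueError("abundances must be positive")
            if not set(seq) <= set("ACGT"):
                raise ValueError("template sequences must be plain ACGT")

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.members]

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.members])


@dataclass
class SimConfig:
    n_reads: int = 5000
    pcr_cycles: int = 25
    #: per-base per-cycle substitution probability; the real per-cycle
    #: polymerase error rate is not printed anywhere we can cite, so this
    #: default is a stated assumption in the 1e-5..1e-4 range
    pcr_error_rate: float = 5e-5
    chimera_rate: float = 0.0
    #: per-tag 5'-truncation probability; either one global float or a
    #: mapping of tag name -> rate (e.g. {"5-v6R": 0.305})
    tag_n1_rate: float | Mapping[str, float] = 0.0
    read_length: int = 76
    #: linear Phred decay with distance from the sequencing primer
    phred_start: float = 38.0
    phred_decay: float = 0.12
    phred_jitter: float = 2.0
    sequencing_errors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def n1_rate_for(self, tag_name: str) -> float:
        if isinstance(self.tag_n1_rate, Mapping):
            return float(self.tag_n1_rate.get(tag_name, 0.0))
        return float(self.tag_n1_rate)


@dataclass
class ReadTruth:
    read_id: str
    sample_id: str
    source_index: int
    pcr_substitutions: list[int] = field(default_factory=list)
    chimera: bool = False
    chimera_parents: tuple[int, int] | None = None
    left_tag_truncated: bool = False
    right_tag_truncated: bool = False
    n_seq_errors_r1: int = 0
    n_seq_errors_r2: int = 0


@dataclass
class TruthManifest:
    reads: list[ReadTruth] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(r) for r in self.reads], fh)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            rows = json.load(fh)
        reads = []
        for r in rows:
            if r.get("chimera_parents") is not None:
                r["chimera_parents"] = tuple(r["chimera_parents"])
            reads.append(ReadTruth(**r))
        return cls(reads)

    def by_id(self) -> dict[str, ReadTruth]:
        return {r.read_id: r for r in self.reads}


def _quality_vector(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    pos = np.arange(cfg.read_length)
    q = cfg.phred_start - cfg.phred_decay * pos
    q = q + rng.normal(0.0, cfg.phred_jitter, size=cfg.read_length)
    return np.clip(np.rint(q), 2, 41).astype(int)


def _sequence_read(seq: str, rng: np.random.Generator, cfg: SimConfig) -> tuple[str, list[int], int]:
    """Apply the position-dependent quality profile and miscalls to one read."""
    qual = _quality_vector(rng, cfg)
    n_err = 0
    if cfg.sequencing_errors:
        p_err = 10.0 ** (-qual / 10.0)
        hits = np.nonzero(rng.random(cfg.read_length) < p_err)[0]
        if hits.size:
            chars = list(seq)
            for i in hits:
                choices = [b for b in "ACGT" if b != chars[i]]
                chars[i] = choices[rng.integers(3)]
            seq = "".join(chars)
            n_err = int(hits.size)
    return seq, qual.tolist(), n_err


def simulate_run(
    communities: Mapping[str, CommunityProfile],
    sheet: SampleSheet,
    tags: TagTable,
    primers: PrimerPair,
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthManifest]:
    """Generate one synthetic run: (R1 records, R2 records, manifest).

    Deterministic for a fixed ``config.seed``.
    """
    sheet.validate_against(tags)
    missing = [s for s in sheet.sample_ids if s not in communities]
    if missing:
        raise ValueError(f"samples without a community: {missing}")

    rng = np.random.default_rng(config.seed)
    r_pos = primers.left.find("R")
    r1_out: list[SequenceRecord] = []
    r2_out: list[SequenceRecord] = []
    manifest = TruthManifest()

    for left_name, right_name, sample in sheet.rows:
        comm = communities[sample]
        ltag_full = tags.by_name("left", left_name).seq
        rtag_full = tags.by_name("right", right_name).seq
        l_n1 = config.n1_rate_for(left_name)
        r_n1 = config.n1_rate_for(right_name)
        # the primer's degenerate position is a property of the template
        # molecule being amplified, fixed per reference
        r_real = rng.choice(["A", "G"], size=len(comm.members))
        p = comm.abundances

        src_draws = rng.choice(len(comm.members), size=config.n_reads, p=p)
        for j in range(config.n_reads):
            read_id = f"{sample}_read{j}"
            truth = ReadTruth(read_id=read_id, sample_id=sample, source_index=int(src_draws[j]))

            src = int(src_draws[j])
            template = comm.sequences[src]
            if config.chimera_rate and rng.random() < config.chimera_rate and len(comm.members) > 1:
                other = int(rng.choice(len(comm.members), p=p))
                while other == src:
                    other = int(rng.choice(len(comm.members), p=p))
                a, b = comm.sequences[src], comm.sequences[other]
                bp = int(rng.integers(1, min(len(a), len(b))))
                template = a[:bp] + b[bp:]
                truth.chimera = True
                truth.chimera_parents = (src, other)

            lprimer = primers.left
            if r_pos >= 0:
                lprimer = lprimer[:r_pos] + r_real[src] + lprimer[r_pos + 1:]

            ltag = ltag_full
            if l_n1 and rng.random() < l_n1:
                ltag = ltag[1:]
                truth.left_tag_truncated = True
            rtag = rtag_full
            if r_n1 and rng.random() < r_n1:
                rtag = rtag[1:]
                truth.right_tag_truncated = True

            amplicon = ltag + lprimer + template + revcomp(primers.right) + revcomp(rtag)
            if len(amplicon) > 2 * config.read_length - 10:
                raise ValueError(
                    f"amplicon length {len(amplicon)} leaves <10 nt overlap at "
                    f"read length {config.read_length}"
                )

            if config.pcr_error_rate:
                # lineage model: pcr_cycles independent chances to substitute
                # each base
                n_sub = rng.binomial(len(amplicon) * config.pcr_cycles, config.pcr_error_rate)
                if n_sub:
                    chars = list(amplicon)
                    positions = rng.integers(0, len(amplicon), size=n_sub)
                    for pos in positions:
                        choices = [b for b in "ACGT" if b != chars[pos]]
                        chars[pos] = choices[rng.integers(3)]
                        truth.pcr_substitutions.append(int(pos))
                    amplicon = "".join(chars)

            r1_seq = amplicon[: config.read_length]
            r2_seq = revcomp(amplicon)[: config.read_length]
            r1_seq, r1_qual, e1 = _sequence_read(r1_seq, rng, config)
            r2_seq, r2_qual, e2 = _sequence_read(r2_seq, rng, config)
            truth.n_seq_errors_r1 = e1
            truth.n_seq_errors_r2 = e2

            r1_out.append(SequenceRecord(id=read_id, seq=r1_seq, qual=r1_qual))
            r2_out.append(SequenceRecord(id=read_id, seq=r2_seq, qual=r2_qual))
            manifest.reads.append(truth)

    return r1_out, r2_out, manifest


# ---------------------------------------------------------------------------
# bundled fixture

# Synthetic V6-like inter-primer templates, 72-92 nt. t0-t3 form a strain
# cluster differing pairwise by 1-2 substitutions (emulating the
# single-nucleotide strain variants that dominate real vaginal samples);
# the rest are mutually distant.
_FIXTURE_TEMPLATES = [
    # t0 (76 nt) and three 1-substitution variants
    "ACGGTCAAGACTTCGGTAGGTAACCTGCCTTACAGCGAGGGATAACTATTGGAAACGATAGCTAATACCGCATAAC",
    "ACGGTCAAGACTTCGGTAGGTAACCTGCCTTACAGCGAGGGATAACTATTGGAAACGATAGCTAATACCGCATGAC",
    "ACGGTCAAGACTTCGGTAGGTAACCTGCCTTACAGCGAGGGATAACTATTGGAAACGATAGCTAATACCGTATAAC",
    "ACGGTCAAGACTTCGGTAGGTAACCAGCCTTACAGCGAGGGATAACTATTGGAAACGATAGCTAATACCGCATAAC",
    # distant templates of varying length (72-92 nt)
    "TTGACGTTACCCGCAGAAGAAGCACCGGCTAACTCCGTGCCAGCAGCCGCGGTAATACGGAGGGTGCAAGCG",
    "GGAATATTGCACAATGGGCGCAAGCCTGATGCAGCCATGCCGCGTGTATGAAGAAGGCCTTCGGGTTGTAAAGTACTTT",
    "CCTACGGGAGGCAGCAGTGGGGAATATTGCACAATGGGGGAAACCCTGATGCAGCGACGCCGCGTGAGTGATGAAGG",
    "GACTCCTACGGGAGGCTGCAGTGGGGAATATTGGACAATGGGCGAAAGCCTGATCCAGCCATGCCGCGTGAGTGAAGAAGGCCTTAGGG",
    "TAGGGAATCTTCCACAATGGACGAAAGTCTGATGGAGCAACGCCGCGTGAGTGAAGAAGGTTTTCGGATCGTAAAGCTCTGTTG",
    "CGCGGTAATACGTAGGTGGCAAGCGTTATCCGGATTTATTGGGCGTAAAGCGAGCGCAGGCGGTTTCTTAAGTCTGATG",
]


def default_fixture(n_samples: int = 6) -> tuple[dict[str, CommunityProfile], SampleSheet]:
    """A small bundled study: 10 V6-like templates, six samples on a
    3 left x 2 right tag grid, with uneven per-sample communities."""
    tags = default_tag_table()
    lefts = ["0-v6L", "1-v6L", "3-v6L"]
    rights = ["0-v6R", "5-v6R"]
    rows = []
    for i in range(n_samples):
        rows.append((lefts[i % 3], rights[i // 3 % 2], f"sample{i + 1}"))
    sheet = SampleSheet(rows)
    sheet.validate_against(tags)

    # staggered community compositions: some dominated by the strain
    # cluster, some more even
    compositions = [
        {0: 0.55, 1: 0.25, 4: 0.15, 6: 0.05},
        {0: 0.40, 2: 0.20, 3: 0.15, 5: 0.15, 7: 0.10},
        {4: 0.50, 5: 0.30, 8: 0.20},
        {0: 0.70, 1: 0.10, 2: 0.10, 9: 0.10},
        {5: 0.35, 6: 0.25, 7: 0.20, 8: 0.12, 9: 0.08},
        {0: 0.30, 4: 0.30, 5: 0.20, 8: 0.20},
    ]
    communities = {
        f"sample{i + 1}": CommunityProfile(
            [(_FIXTURE_TEMPLATES[k], v) for k, v in comp.items()]
        )
        for i, comp in enumerate(compositions[:n_samples])
    }
    return communities, sheet
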