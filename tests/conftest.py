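"""Shared fixtures: small simulated runs carried through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from v6prof.demux import PrimerPair, demux_run
from v6prof.derep_cluster import ISU, OTU, cluster_otus, dereplicate
from v6prof.formats import TagTable, default_tag_table
from v6prof.merge import CompositeRead, MergeStats, merge_run
from v6prof.simulate import SimConfig, TruthManifest, default_fixture, simulate_run


@dataclass
class ChainResult:
    """Everything produced by running a simulated run through demux."""

    r1: list
    r2: list
    manifest: TruthManifest
    composites: list[CompositeRead]
    merge_stats: MergeStats
    records: list
    demux_stats: object
    isus: list[ISU]
    otus: list[OTU]


def run_chain(communities, sheet, tags, primers, cfg, threshold=0.95) -> ChainResult:
    r1, r2, manifest = simulate_run(communities, sheet, tags, primers, cfg)
    composites, mstats = merge_run(zip(r1, r2))
    eligible = [c for c in composites if c.status == "perfect"]
    records, dstats = demux_run(eligible, tags, primers, sheet)
    isus, _ = dereplicate((r.sample_id, r.interprimer_seq) for r in records)
    otus = cluster_otus(isus, threshold) if isus else []
    return ChainResult(r1, r2, manifest, composites, mstats, records, dstats, isus, otus)


@pytest.fixture(scope="session")
def tags() -> TagTable:
    return default_tag_table()


@pytest.fixture(scope="session")
def primers() -> PrimerPair:
    return PrimerPair()


@pytest.fixture(scope="session")
def fixture6():
    return default_fixture()


@pytest.fixture(scope="session")
def clean_chain(fixture6, tags, primers) -> ChainResult:
    """Noise-free six-sample run, 500 reads per sample."""
    communities, sheet = fixture6
    cfg = SimConfig(
        n_reads=500, pcr_error_rate=0.0, chimera_rate=0.0,
        sequencing_errors=False, seed=101,
    )
    return run_chain(communities, sheet, tags, primers, cfg)


@pytest.fixture(scope="session")
def noisy_chain(fixture6, tags, primers) -> ChainResult:
    """Six-sample run with PCR error, sequencing error, chimeras and N-1
    tag truncation all switched on."""
    communities, sheet = fixture6
    cfg = SimConfig(
        n_reads=1500, pcr_error_rate=5e-5, chimera_rate=0.005,
        tag_n1_rate={"5-v6R": 0.305}, sequencing_errors=True, seed=202,
    )
    return run_chain(communities, sheet, tags, primers, cfg)


@pytest.fixture(scope="session")
def clean_sheet(fixture6):
    return fixture6[1]
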