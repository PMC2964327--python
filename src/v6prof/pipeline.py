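"""End-to-end orchestration: merge -> demux -> derep -> cluster -> profiles
-> (chimera) -> diversity -> (taxonomy), with a conservation ledger.

Every stage boundary is audited: the number of records entering a stage
must equal the eligible output of the previous one, and classified
rejects plus survivors must add back up to the input. The run report
serializes the ledger together with every stage's statistics and the
configuration used, so a run is fully reproducible from its report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chimera import apply_cutoff, read_score_table
from .demux import PrimerPair, demux_run
from .derep_cluster import cluster_otus, dereplicate, otu_count_table
from .diversity import saturation_report
from .error_profile import (
    EntropyCutoffs,
    decay_curve,
    entropy_stats,
    flag_error_otus,
    primer_decay,
    primer_profile,
    profile_positions,
)
from .formats import (
    SampleSheet,
    SequenceRecord,
    TagTable,
    default_tag_table,
    write_fasta,
    write_fastq,
)
from .merge import merge_files, merge_run

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    fastq_r1: str = ""
    fastq_r2: str = ""
    tag_table: str = ""  # TSV path; empty -> bundled published tag set
    sample_sheet: str = ""
    left_primer: str = ""
    right_primer: str = ""
    min_overlap: int = 10
    max_overlap: int = 50
    max_primer_mm: int = 3
    identity_threshold: float = 0.95
    entropy_skew_cutoff: float = 1.5
    entropy_sigma_cutoff: float = 4.5
    entropy_q_cutoff: float = 3.0
    ghost_ratio_cutoff: float = 100.0
    chimera_scores: str = ""  # optional score table path
    chimera_cutoff: float = 10.0
    n_resamples: int = 10000
    min_rarefaction_count: int = 1
    saturation_threshold: float = 0.97
    profile_top_n: int = 25
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def primers(self) -> PrimerPair:
        kwargs = {}
        if self.left_primer:
            kwargs["left"] = self.left_primer
        if self.right_primer:
            kwargs["right"] = self.right_primer
        return PrimerPair(**kwargs)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    pairs=None,
    tags: TagTable | None = None,
    sheet: SampleSheet | None = None,
) -> dict:
    """Run all stages and write the report plus per-stage tables.

    Inputs may come from the configured FASTQ paths or be passed in-memory
    (``pairs`` as an iterable of record pairs). Returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "ledger": {}, "stages": {}}
    ledger = report["ledger"]

    tags = tags or (TagTable.from_tsv(config.tag_table) if config.tag_table else default_tag_table())
    if sheet is None:
        if not config.sample_sheet:
            raise PipelineError("config: no sample sheet given")
        sheet = SampleSheet.from_tsv(config.sample_sheet)
    primers = config.primers()

    # --- merge ------------------------------------------------------------
    try:
        if pairs is not None:
            composites, merge_stats = merge_run(
                pairs, config.min_overlap, config.max_overlap
            )
        else:
            composites, merge_stats = merge_files(
                config.fastq_r1, config.fastq_r2,
                min_overlap=config.min_overlap, max_overlap=config.max_overlap,
            )
    except Exception as exc:
        raise PipelineError(f"merge: {exc}") from exc
    report["stages"]["merge"] = dataclasses.asdict(merge_stats)
    ledger["pairs_in"] = merge_stats.n_pairs
    ledger["merge_partition_ok"] = (
        merge_stats.perfect + merge_stats.one_mismatch + merge_stats.unmerged
        == merge_stats.n_pairs
    )
    eligible = [c for c in composites if c.status == "perfect"]
    write_fastq((c.to_record() for c in eligible), out_dir / "composites.fastq")

    # --- demux ------------------------------------------------------------
    try:
        records, demux_stats = demux_run(
            eligible, tags, primers, sheet, config.max_primer_mm
        )
    except Exception as exc:
        raise PipelineError(f"demux: {exc}") from exc
    report["stages"]["demux"] = demux_stats.as_dict()
    ledger["composites_in"] = demux_stats.n_input
    ledger["demux_input_matches_merge"] = demux_stats.n_input == merge_stats.perfect
    ledger["demux_partition_ok"] = (
        demux_stats.n_assigned + sum(demux_stats.failures.values())
        == demux_stats.n_input
    )

    # --- dereplicate + cluster --------------------------------------------
    try:
        isus, _index = dereplicate((r.sample_id, r.interprimer_seq) for r in records)
        otus = cluster_otus(isus, config.identity_threshold)
    except Exception as exc:
        raise PipelineError(f"cluster: {exc}") from exc
    n_isu_reads = sum(i.total_count for i in isus)
    n_otu_reads = sum(o.total_count for o in otus)
    ledger["reads_demuxed"] = demux_stats.n_assigned
    ledger["derep_conserved"] = n_isu_reads == demux_stats.n_assigned
    ledger["cluster_conserved"] = n_otu_reads == n_isu_reads
    report["stages"]["cluster"] = {
        "n_isus": len(isus),
        "n_otus": len(otus),
        "most_abundant_isu_reads": isus[0].total_count if isus else 0,
    }
    write_fasta(
        (SequenceRecord(id=f"isu_{i.isu_id}_count_{i.total_count}", seq=i.seq) for i in isus),
        out_dir / "isus.fasta",
    )
    write_fasta(
        (
            SequenceRecord(
                id=f"otu_{o.otu_id}_count_{o.total_count}", seq=isus[o.seed_isu_id].seq
            )
            for o in otus
        ),
        out_dir / "otu_seeds.fasta",
    )
    samples = sheet.sample_ids
    table = otu_count_table(otus, samples)
    table.to_tsv(out_dir / "otu_counts.tsv")
    with open(out_dir / "otu_members.tsv", "w") as fh:
        fh.write("otu_id\tisu_id\tdistance\tidentity\n")
        for o in otus:
            for isu_id, dist, ident in o.members:
                fh.write(f"{o.otu_id}\t{isu_id}\t{dist}\t{ident:.4f}\n")

    # --- error profiles ---------------------------------------------------
    cutoffs = EntropyCutoffs(
        skew=config.entropy_skew_cutoff,
        sigma=config.entropy_sigma_cutoff,
        q=config.entropy_q_cutoff,
    )
    try:
        prof_rows = []
        for otu in otus[: config.profile_top_n]:
            profile = profile_positions(otu, isus)
            est = entropy_stats(profile, cutoffs)
            curve = decay_curve(otu, isus)
            prof_rows.append(
                {
                    "otu_id": otu.otu_id,
                    "n_reads": otu.total_count,
                    "mean_entropy": est.mean,
                    "median_entropy": est.median,
                    "max_entropy": est.max,
                    "skew": est.skew,
                    "sigma": est.sigma,
                    "q": est.q,
                    "classification": est.classification,
                    "decay": curve.fractions.tolist(),
                }
            )
        ghosts = flag_error_otus(otus, isus, config.ghost_ratio_cutoff)
        for row in prof_rows:
            if row["otu_id"] in ghosts:
                row["classification"] = "pcr_ghost"
        lprof, rprof = primer_profile(records, primers)
        pdecay = primer_decay(records, primers)
    except Exception as exc:
        raise PipelineError(f"profile: {exc}") from exc
    report["stages"]["error_profile"] = {
        "otu_stats": prof_rows,
        "pcr_ghost_otus": ghosts,
        "primer_decay": pdecay.fractions.tolist(),
        "primer_left_consensus": lprof.consensus,
        "primer_right_consensus": rprof.consensus,
    }

    # --- chimera (optional) -----------------------------------------------
    if config.chimera_scores:
        try:
            chim_records = read_score_table(config.chimera_scores)
            summary = apply_cutoff(chim_records, isus, config.chimera_cutoff)
        except Exception as exc:
            raise PipelineError(f"chimera: {exc}") from exc
        report["stages"]["chimera"] = {
            "n_isus_flagged": summary.n_isus_flagged,
            "n_reads_flagged": summary.n_reads_flagged,
            "pct_isus": summary.pct_isus,
            "pct_reads": summary.pct_reads,
        }

    # --- diversity ----------------------------------------------------------
    try:
        sample_counts = {
            s: [c for c in table.df.loc[s].tolist() if c > 0] for s in samples
            if table.df.loc[s].sum() > 0
        }
        sat = saturation_report(
            sample_counts,
            limit_threshold=config.saturation_threshold,
            n_resamples=min(config.n_resamples, 1000),
            seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError(f"diversity: {exc}") from exc
    sat.to_csv(out_dir / "saturation.tsv", sep="\t")
    report["stages"]["diversity"] = {
        "n_samples": int(len(sat)),
        "n_flagged": int(sat["flagged"].sum()),
        "mean_limit_rarefaction": float(sat["limit_rarefaction"].mean()),
    }

    ledger["all_conserved"] = all(
        ledger[k]
        for k in (
            "merge_partition_ok",
            "demux_input_matches_merge",
            "demux_partition_ok",
            "derep_conserved",
            "cluster_conserved",
        )
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
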