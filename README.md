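# v6prof

Combinatorially sequence-tagged, paired-end **16S rRNA V6 amplicon
profiling**: a complete analysis pipeline for microbiome runs in which each
sample is coded by a *pair* of short (3–6 nt) sequence tags, one on each PCR
primer, and the two 76-nt Illumina reads of every amplicon overlap in the
middle.

The pipeline is aimed at microbial-ecology and clinical-microbiome groups
who sequence short hypervariable regions at great depth and need to know
which of the resulting sequence variants are organisms and which are PCR
artifacts.

## What it does

1. **Overlap merging.** Each read pair is merged into a composite amplicon
   read by scanning overlap lengths from 50 down to 10 nt. Bases called
   identically by both reads get the *sum* of their Phred scores
   (independent concordant observations of a log-odds score are additive),
   capped at 90; at a single tolerated mismatch the higher-quality base
   wins. Only perfect-overlap composites continue downstream.
2. **Dual-tag demultiplexing.** A composite is assigned to a sample when an
   exact full-length left tag and right tag flank the two primers
   (`CAACGCGARGAACCTTACC`, *E. coli* 967–985, and `ACAACACGAGCTGACGAC`,
   1078–1061), each with at most 3 IUPAC-aware mismatches. Failures are
   classified (N-1 truncated tag, absent tag, extra 5′ bases, tag mismatch,
   primer failure, pair not in sheet) so the classes always partition the
   rejects. Tag sets are validated for N-1 truncation collisions and
   first-four-position base balance.
3. **ISU dereplication and OTU clustering.** Identical inter-primer
   sequences collapse into ISUs (individual sequence units), ranked by
   abundance. ISUs are clustered greedily around abundance-ordered seeds at
   a configurable identity threshold; identity is `1 − d/max(len)` with `d`
   the Levenshtein distance, so at the default 95% a 76-mer may differ from
   its seed by up to 3 edits. A Levenshtein matrix and neighbour-joining
   tree over the abundant ISUs support choosing the threshold.
4. **Error anatomy.** Per-OTU positional nucleotide profiles, Shannon
   entropy summaries (skew, σ = standardized entropy maximum,
   q = robust percentile analogue), mismatch-decay curves against the
   primer-region baseline, and detection of *PCR-ghost* OTUs — clusters
   whose seed is outnumbered ~100× by members 2–3 edits away, i.e. shards
   of an abundant neighbour's error cloud.
5. **Chimeras, diversity, taxonomy.** Externally computed chimera scores
   are thresholded and summarized; per-sample bootstrap rarefaction
   curves, Chao1/ACE richness and saturation flags are computed; and OTU
   seeds are classified from BLAST hit tables with explicit
   species/genus/LCA rules suited to 72–92 nt queries. The N-1 tag
   synthesis error doubles as a free technical replicate: reads carrying
   the truncated tag variant are an independent draw from the same tube.
6. **Simulation.** A bundled generator emulates the whole process —
   multinomial community sampling, per-template realization of the
   degenerate primer position, lineage-model PCR substitutions over 25
   cycles, within-sample chimeras, N-1 tag truncation, and
   position-decaying Phred quality with matched miscalls — and emits a
   ground-truth manifest, so every stage is testable end to end without
   external data.

## Worked example

```python
from v6prof import (PrimerPair, SimConfig, default_fixture, default_tag_table,
                    simulate_run, run_pipeline, PipelineConfig)

communities, sheet = default_fixture()          # 10 templates, 6 samples
tags = default_tag_table()
cfg = SimConfig(n_reads=2000, pcr_error_rate=5e-5, chimera_rate=0.005,
                tag_n1_rate={"5-v6R": 0.305}, seed=11)
r1, r2, truth = simulate_run(communities, sheet, tags, PrimerPair(), cfg)
report = run_pipeline(PipelineConfig(seed=1), "out/", pairs=zip(r1, r2),
                      tags=tags, sheet=sheet)
print(report["stages"]["merge"])
print(report["stages"]["cluster"])
```

prints (seed 11):

```
{'n_pairs': 12000, 'perfect': 11408, 'one_mismatch': 575, 'unmerged': 17,
 'low_quality_containing': 5}
{'n_isus': 834, 'n_otus': 42, 'most_abundant_isu_reads': 2758}
```

95.1% of the 12 000 simulated pairs merge with a perfect overlap; 575 are
rescued only by the one-mismatch pass (and are excluded downstream); the
9 489 demultiplexed reads collapse to 834 ISUs — the 10 real templates plus
a tail of PCR/sequencing-error variants — which cluster into 42 OTUs. The
most abundant OTU (the four-strain cluster differing by single diagnostic
nucleotides) is classified *mixed* by its entropy statistics, while
single-template OTUs classify *homogeneous*, and the conservation ledger in
`report["ledger"]` confirms that read counts balance at every stage
boundary.

The same stages are exposed as a CLI:

```sh
v6prof simulate --out-dir run/ --n-reads 5000 --seed 1
v6prof pipeline --r1 run/reads_R1.fastq --r2 run/reads_R2.fastq \
                --sheet run/sheet.tsv --out-dir results/
v6prof validate-tags --side left
```

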