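# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data generator does and does
not emulate.

## Amplicon model and read merging

An amplicon is `left_tag + left_primer + V6 + revcomp(right_primer) +
revcomp(right_tag)`; with 3–6 nt tags, 19+18 nt primers and a 72–92 nt V6
insert its length is 102–142 nt, so two 76-nt reads overlap by 10–50 nt.
The merger scans overlap lengths **longest-first** and accepts the first
perfect overlap; if none exists it rescans allowing exactly one mismatch.
Longest-first is a deliberate tie-break among feasible placements: it
maximizes the evidence supporting the merge and is deterministic. In
agreeing overlap positions the merged Phred score is `min(q1+q2, 90)` —
Phred scores are log-odds, so independent concordant calls add; the cap
keeps scores encodable in Phred+33. At the single tolerated mismatch the
base with the higher Phred wins and keeps its own score (ties keep the
forward base). An `N` matches nothing, including another `N`, so a perfect
overlap can never contain one. One-mismatch merges are counted but
excluded from all downstream stages.

Quality encoding is fixed to Sanger Phred+33; the historical +64 dialect is
available only by explicit argument, never auto-detected.

## Demultiplexing

Tag matching is exact and full-length; the primer that follows
(respectively precedes, on the reverse-complemented 3′ side) may carry up
to 3 IUPAC-aware mismatches. Among multiple candidate tags the one with the
fewest primer mismatches wins, then the longest tag. A read whose matched
tag is also the N-1 truncation of a longer tag in the set (GTA/CTA/TGA vs
AGTA/GCTA/ATGA in the bundled table) is kept but flagged `n1_ambiguous`;
a switch excludes such reads instead. Rejected reads are classified into
exactly one failure class using a fixed priority order (N-1 truncation,
absent tag, extra 5′ bases, tag mismatch, primer failure, pair not in
sheet) so that the histogram always partitions the rejects; the order is a
determinism decision, since the classes themselves do not define one.

IUPAC semantics are asymmetric by design: a degenerate primer letter
matches any base in its set, while an `N` in a read matches nothing. All
reported coordinates are 1-based and inclusive, in the usual *E. coli* 16S
numbering (left primer 967–985, right primer 1078–1061).

Reference-coverage scanning (`primer_coverage`) requires a perfect match at
the five 3′-terminal primer bases — the polymerase-extension end, where
mismatches are least tolerated — and ≤2 (configurable) mismatches
elsewhere.

## Clustering

Identity between sequences is `1 − Levenshtein/max(len)`. The max-length
denominator is symmetric and conservative (alternative conventions differ
across clustering tools). ISUs are visited from most to least abundant;
each joins the existing seed of **highest** identity at or above the
threshold (best-hit, not first-hit: assignment is then stable when a new
seed appears later in the scan), with ties going to the lower OTU id.
Abundance ordering rests on the assumption that the most-sequenced variant
of a cloud is the error-free one. At the default 0.95 threshold a 76-mer
may differ from its seed by 3 edits; lowering the threshold can only merge
clusters, never split them.

The abundant-ISU edit-distance matrix takes every ISU reaching a relative
frequency of `min_sample_freq` (default 0.01; configurable — no published
value exists for this cutoff) in at least one sample. Neighbour joining is
Saitou–Nei (via scikit-bio), with negative branch lengths clamped to zero.

## Error anatomy

**Positional profiles.** OTU members are globally aligned to their seed
with unit edit costs. Both sequences are padded with a fixed 6-base flank
on each side before alignment and the flank columns are dropped afterwards,
which stops terminal gaps from being smeared into the first and last
profile columns. Member bases at aligned seed positions accumulate
read-count weight; insertions relative to the seed are discarded and
deletions contribute nothing at the deleted position.

**Entropy statistics.** Per-position Shannon entropy is computed in bits
(0 = unanimous, 2 = uniform). Three summaries describe the entropy vector
`h`:

* `skew` — standardized third moment, using population (biased) moments
  for determinism;
* `sigma = (max h − mean h) / sd(h)`;
* `q = (max h − median h) / (p95(h) − median h)`, with p95 by linear
  interpolation over all positions including zeros.

`sigma` and `q` are defined as 0 when their denominators vanish. An OTU is
*mixed* when any statistic crosses its cutoff, else *homogeneous*.

**Cutoff defaults (skew 1.5, sigma 4.5, q 3.0).** These were calibrated
against the null: for a profile of L≈76 positions whose entropies are
i.i.d. noise around a flat error floor, the expected maximum sits ~2.4–3.5
standard deviations above the mean simply because it is the max of ~76
draws — so a sigma cutoff of 3 fires on a quarter of genuinely
single-template OTUs. Measured on 50 error-only single-template replicates
of the simulator at default depth, the null maxima were sigma 4.1, q 2.8,
skew 1.4; true two-template mixtures (10% minor, 2 diagnostic positions)
give sigma ≥ 3.6 with median q ≈ 25. The defaults sit just above the null
extremes and far below the mixture signal, and recover ≥95% correct
classifications in the seeded parameter-recovery test. All three are
configurable.

**Decay curves and ghosts.** The fraction of an OTU's reads at each edit
distance from its seed decays monotonically when variation is pure
PCR/sequencing error (each additional error multiplies the probability by
a small factor); a genuine second taxon appears as a mass spike at its
distance. The 37-nt concatenated primer regions provide an in-run baseline
for this decay. A *PCR-ghost* OTU — flagged when members at distance ≥2
outnumber the seed by ≥100× (configurable) — is the shard of an abundant
template's error cloud that fell outside the identity threshold.

## Chimeras

No detector is implemented; scores from an external tool (UCHIME-style
tables) are thresholded at `score ≥ cutoff` (default 10; boundary inclusion
is this package's documented choice) and summarized as flagged ISU and read
counts and percentages. In simulations, chimeras are verified through the
truth manifest instead. Note that a splice between near-identical templates
frequently reproduces a parent sequence exactly; only novel spliced
sequences are observable as chimeric.

## Diversity

Rarefaction is bootstrap resampling **with replacement** (default 10 000
resamples; the depth grid is 20 evenly spaced points up to the sample
total). The expected distinct-feature count at depth *d* has the closed
form Σᵢ (1 − (1 − pᵢ)^d), which the tests use as the Monte-Carlo oracle.
With replacement, the curve reaches the observed richness only for
saturated samples, so `limit_rarefaction` (mean rarefied richness at full
depth over observed richness) below 0.97 flags an under-sampled sample.
An optional min-count filter of 3 drops features seen at most twice before
resampling.

Chao1 is reported classic and bias-corrected; ACE uses the standard rare
cutoff of 10. Two degenerate ACE cases are handled explicitly: no rare
features at all → ACE = S_obs; all rare features singletons (ACE undefined)
→ bias-corrected Chao1 is substituted.

Technical-replicate correlation exploits the N-1 tag synthesis error: the
truncated-tag reads are a binomial split of the same PCR. Pearson *r* is
computed on log10 counts (the natural scale for abundances spanning orders
of magnitude) over OTUs with ≥30 reads in the full-length and ≥10 in the
N-1 pseudo-sample; with fewer than 3 qualifying OTUs the correlation is
reported as undefined rather than a number.

## Taxonomy

Rules for 72–92 nt queries from a BLAST hit table: species requires a 100%
identity, 100% coverage hit with no different-species hit within
`margin_identity` (default 1.0 percentage point — the exclusion window is
configurable, as no authoritative value exists) of 100; genus requires top
identity ≥95% with all within-margin hits in one genus; otherwise the
lowest common lineage level of the within-margin hits is assigned.
Lineages come from a local subject→lineage table; subjects annotated
uncultured/environmental can be pre-filtered.

## The simulator

What it emulates: multinomial sampling from fixed per-sample communities;
per-template realization of the degenerate primer position (R drawn once
per reference as A or G, so the observed split at that position reflects
template composition, not error); PCR substitutions via a lineage model —
each read descends through `pcr_cycles` replications, each able to
substitute any base, giving Binomial(L×cycles, rate) substitutions per read
with expectation L×cycles×rate; within-sample chimeras spliced at one
uniform breakpoint; per-tag N-1 truncation; and sequencing miscalls at
rate 10^(−Q/10) under a linearly decaying Phred profile with Gaussian
jitter. All randomness flows from one seeded generator; a fixed seed
reproduces the FASTQ byte for byte, and a JSON manifest records every
injected event per read.

Stated assumptions (not literature values): the per-base per-cycle PCR
substitution rate defaults to 5×10⁻⁵ (polymerase fidelity is typically
quoted in the 10⁻⁵–10⁻⁴ range); the quality profile starts at Q38 and
decays 0.12 per position with σ=2 jitter. PCR errors are applied uniformly
across the whole amplicon; in reality the primer-region bases are carried
by the synthetic oligo in half the final molecules and so see roughly half
the effective error rate — a simplification that does not affect the
monotone shape of the primer-decay baseline.

What it does not emulate: indel and homopolymer errors (a pyrosequencing
failure mode, not an Illumina one), cross-sample chimeras, flow-cell
spatial artifacts, GC-dependent amplification bias, and quality-score
miscalibration. Passing tests therefore demonstrate correctness of the
analysis under a substitution-dominated error model with honest quality
scores; they do not certify behaviour on data violating those assumptions.

## Problem sizes in the test suite

The bundled study runs six samples over ten 72–92 nt templates (including
a four-member single-nucleotide strain cluster). The exact-recovery test
uses 6×20 000 noise-free reads; the entropy parameter-recovery test uses
100 seeded classifications at 3 000 reads per replicate (the depth of an
abundant OTU at desk scale); rarefaction checks use 10 000 resamples; the
end-to-end acceptance study uses 6×8 000 reads with every error process
enabled. These sizes were chosen so each check exercises the statistics at
realistic depth while the whole suite stays comfortably reproducible on a
single CPU.
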