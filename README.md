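# asmqual

Reference-free quality scoring of genome assemblies from paired-end read
mapping and supervised regression.

## The problem

Choosing among several assemblies of the same genome — or deciding whether a
draft chromosome is good enough to build on — usually means either comparing
against a trusted reference (which de novo projects don't have) or juggling a
dozen incommensurable statistics (N50, gap percent, clip rate, ...).
`asmqual` collapses that panel into a single comparable quality score per
assembled sequence. The score is learned: assemblies with trusted references
are scored by direct sequence comparison, a regression model is fitted from
read-mapping metrics to those reference-based scores, and the fitted model
then scores assemblies that have *no* reference — only a FASTA and a
paired-end Illumina library (≥ 10×, insert ≈ 350–550 bp) are needed.

It is aimed at genome-assembly practitioners: rank assembler outputs, pick a
reference build for an organism, or watch a chromosome's quality across
assembly versions — including comparisons *across* organisms, as long as one
model scored them all.

## The method

**Metrics.** For each assembly, 13 metrics are computed:

* contiguity/completeness, from sequence alone: `normN50` (N50 as % of total
  length), `gap_perc`, `norm_contig_number`;
* accuracy, from mapped read pairs: `prop_pair_perc` (properly paired reads /
  mapped reads), and per-base error evidence converted to percent of bases —
  `clip` (clustered soft-clip points), `low_read_cov`, `low_fc_in_contig` /
  `low_fc_over_gap` (low physical fragment coverage, inside contigs vs over
  gaps), `FCD_err_in_contig` / `FCD_err_over_gap` (fragment-coverage-
  distribution deviation), `links` (pairs joining distant loci),
  `coll_repeat` (collapsed repeats), and `error_free_bases` (positions
  supported by ≥ 5 perfectly matching, unclipped reads and no error flag).

Reads are mapped by a built-in deterministic k-mer seed-and-extend mapper, or
any coordinate-sorted SAM/BAM can be supplied to skip mapping.

**Training targets.** Where a trusted reference exists, the target score is
the percent of matching bases,

    PMB = (L_ref − D) / L_ref × 100,

with `D` the number of reference bases not matched by the query in an
order-preserving alignment. PMB is then scaled twice using each sequence's
Euclidean distance `d` from the ideal metric vector (gap 0, normN50 100,
error-free 100, every error flag 0): within one organism the best (smallest
`d`) chromosome keeps its PMB and every other is multiplied by
`1 − (d − d_best)/D_max`; the same factor, computed from each organism's best
chromosome, then scales across organisms. `D_max` is the fixed ideal-to-worst
distance, so scores remain mutually comparable.

**Model.** The 13 metrics are reduced by a cascade — Pearson filter
(|r| < 0.1 dropped), pairwise-correlation report, joint-mutual-information
(JMIM) ranking, out-of-bag permutation importance (%IncMSE), exhaustive
best-subset linear regression (≤ 6 features, with automatic exclusion of
coefficients whose sign contradicts the marginal correlation). The default
scoring subset is `normN50, gap_perc, clip, error_free_bases,
low_fc_over_gap, low_fc_in_contig`. Six regression families (OLS, elastic
net, KNN, random forest, linear/polynomial SVR) are tuned by cross-validated
RMSE on a shared 80/20 split; the lowest test RMSE wins (random forest with
500 trees in practice) and is refitted on all rows.

Everything is exercised end-to-end without downloads by the built-in
simulators: degraded assemblies (SNPs, indels, CNVs, gaps, fragmentation),
paired-end reads, and full scored training sets.

## Worked example

Simulate a 50 kbp reference, a degraded draft (5 % single-base errors, small
indels, one gap), and a 20× read library; train a model on a synthetic
training set; then score the draft.

```python
from asmqual.simulate import (ErrorProfile, ReadProfile, random_assembly,
                              mutate_assembly, simulate_reads,
                              generate_training_set, write_fastq_pairs)
from asmqual.assembly import write_fasta
from asmqual.model import train_model

ref = random_assembly(1, 50_000, seed=7)
draft, _ = mutate_assembly(ref, ErrorProfile(snp_rate=0.05, indel_rate=0.002,
                                             gap_events=1), seed=8)
reads = simulate_reads(ref, ReadProfile(coverage=20), seed=9)
write_fasta(ref, "ref.fa"); write_fasta(draft, "draft.fa")
write_fastq_pairs(reads, "reads_1.fastq.gz", "reads_2.fastq.gz")

table = generate_training_set(n_genomes=8, ref_length=15_000, seed=11)
results = train_model(table, "rf", seed=0, n_trees=300)
results.save("model")
print(results.summary())
```

```
Assembly quality model
======================
family:          rf
features:        normN50, gap_perc, clip, error_free_bases, low_fc_over_gap, low_fc_in_contig
n observations:  40
tuned params:    {'max_features': 4}
CV RMSE:         2.8427
seed:            0
```

Because this draft *does* have a reference, the learned score can be checked
against the reference-based one:

```bash
$ asmqual refscore --query draft.fa --ref ref.fa
{"ref_length": 50000, "total_differences": 4000, "pmb": 92.0}

$ asmqual score --assembly draft.fa --reads1 reads_1.fastq.gz \
                --reads2 reads_2.fastq.gz --model model
{"granularity": "whole-assembly", "scores": {"__assembly__": 89.3341}}
```

The draft diverges from its source at 4 000 of 50 000 reference bases, so its
reference-based score is 92.0. The model — shown only the draft's mapping
metrics (90.8 % error-free bases, 3.2 % gaps, 3.7 % low-fragment-coverage
bases over gaps) — estimates 89.3, within a few units of the reference-based
truth. A near-perfect sequence scores ≈ 100; scores above 100 are legal and
mean "cleaner than the best training chromosome".

The same commands accept real data: `asmqual metrics` emits the 13-metric
CSV row(s), `--alignments sorted.bam` skips the built-in mapper,
`--per-sequence` scores each scaffold/chromosome separately (the output
always states which granularity was scored), and `--min-identity 0.75` is
recommended when scoring scaffolds rather than chromosomes. `asmqual train`
runs the full cascade + model comparison on any scored metrics table with
the 13 canonical columns; to reproduce the published feature-selection and
model-comparison numbers, place the published 416-instance training table at
`data/evaldna_training_additional_file2.csv` (it is not redistributed here)
— the suite's published-table checks pick it up from that path.

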