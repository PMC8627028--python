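# Methods

## Overview

`asmqual` estimates a genome-assembly quality score in three stages:
(1) compute 13 contiguity/accuracy metrics from the assembly and a mapped
paired-end library; (2) where a trusted reference exists, compute a
reference-based target score (percent matching bases, internally and
externally scaled); (3) fit a regression model from metrics to targets and
apply it to assemblies without references. This note records the model
assumptions, the defaults that matter, and the choices made where the
design was genuinely open.

## Difference counting and the reference-based score

The target score is PMB = (L_ref − D)/L_ref × 100. `D` is defined as the
number of reference bases that cannot be paired with an equal query base in
any order-preserving (monotone) alignment, i.e.

    D = L_ref − LCS(ref, query).

This definition was chosen over "mismatches along one optimal edit path"
because co-optimal edit paths disagree on how many aligned pairs are equal
(e.g. `ACGT` vs `AGCT` admits cost-2 paths with 2 or 3 matches), whereas the
longest common subsequence is a unique, tie-break-free quantity. For a
single substitution D = 1, for a deleted block of b bases D = b; for
clustered substitutions D can be slightly below the substitution count when
an indel-pairing matches more bases, which is the price of determinism.

Implementation: pairs up to ~16 M cells are solved exactly with the
Allison–Dix bit-parallel LCS (O(nm/w) in machine words). Larger pairs are
anchored on 21-mers that are unique in both sequences, chained by longest
increasing subsequence, merged into collinear runs, and the inter-anchor
stretches are solved exactly with the same bit-parallel kernel. If no
anchors exist the sequences are reported fully diverged with a warning.
Multi-scaffold inputs are concatenated in stored order; the simulators
preserve reference order when fragmenting, and externally scaffolded
assemblies should be ordered before scoring (no rearrangement-aware
chaining is attempted).

### Scaling

The published constraint set for score scaling is: the best chromosome of
each organism (smallest Euclidean distance `d` to the ideal metric vector)
keeps its PMB; other chromosomes are scaled down by their distance excess;
the same procedure then runs across organisms using best chromosomes. The
functional form is not fixed by those constraints, so the simplest map
satisfying them is used:

    factor = 1 − (d − d_best) / D_max,   clipped below at 0,

with `D_max` the distance from the ideal vector to the all-worst vector — a
fixed normaliser, so factors are comparable across organisms. The formula is
a config-selectable strategy (`worst_distance` argument), not baked in.

The distance is computed over the 12 percent-scale metrics, each with ideal
0 or 100 and worst the opposite bound (`D_max = √12 × 100 ≈ 346.4`).
`norm_contig_number` is excluded: it is a count per Mbp with no finite worst
bound, and it is uncorrelated with the target anyway (it is dropped by the
Pearson filter). Including it would let a single unbounded coordinate
dominate a Euclidean distance otherwise confined to [0, 100] per axis.

## Read mapping

A deterministic k-mer seed-and-extend mapper, intentionally simple:

| parameter | default | meaning |
|---|---|---|
| `k` | 21 | seed length; seeds occurring > `max_hits` (8) times are masked |
| `seed_step` | read_length/10 | seed spacing along the read |
| `n_candidates` | 3 | top-voted (target, diagonal) clusters aligned |
| `min_identity` | 0.5 | matched fraction of the read below which an alignment is discarded; 0.75 recommended for scaffolds |

Each candidate is first tried ungapped on its exact diagonal (a vectorised
base comparison); if that matches ≥ 75 % of the read it is accepted as is,
otherwise a banded gap-aware alignment (edlib, infix mode, ±15 % pad) is
computed and the read ends are trimmed to the maximal-scoring segment
(+1 match / −2 otherwise), the trimmed ends becoming soft clips. Ties break
by (target id, position), making output independent of hash order. The
practical consequence of exact seeding is a sensitivity cliff: reads from
sequence diverging ≥ ~10–15 % from the target increasingly fail to seed,
so mapped fraction, fragment coverage and error-free bases collapse
together in that range — the same saturation real mappers show and the
reason quality scores fall steeply there rather than linearly.

Proper pairs are defined as: same target, opposite strands,
forward-before-reverse, outer distance within mean ± 3 sd of the library
insert. Insert statistics are estimated from the data (median and
1.4826 × MAD over candidate pairs), so no library declaration is needed.
A coordinate-sorted SAM/BAM may replace the mapper; per-base match calls
are taken from `=`/`X` CIGAR operations when present, else by comparing the
stored read sequence to the assembly, else (no sequence) aligned blocks
count as matches. SAM written by this package uses `=`/`X`, so a
write-then-read round trip reproduces the tracks exactly.

## Error-flag engine

Per-base boolean tracks over each sequence; every percent is flagged bases
divided by total assembly bases.

| flag | rule (defaults) |
|---|---|
| `clip` | ≥ 2 alignments with a clip of ≥ 5 bases anchored within ± 5 bp |
| `low_read_cov` | read depth < 0.25 × global mean read depth |
| `low_fc_*` | fragment depth < 0.25 × global mean fragment depth; runs overlapping a gap run are `over_gap`, else `in_contig` |
| `fcd_err_*` | windowed mean absolute deviation of fragment depth from its local flat fit > 0.3 × mean fragment depth (window = one insert mean); split over gap as above |
| `links` | ≥ 2 spanning reads whose mates map to another sequence or > 10 × insert away |
| `coll_repeat` | fragment depth > 2 × global mean over a run ≥ one insert |
| `error_free` | ≥ 5 unclipped, position-matching reads and no flag set |

Choices worth noting:

* **FCD statistic.** The original fragment-coverage-distribution test is a
  black box; the surrogate here is the windowed mean absolute deviation
  `mad(i) = mean_w(|fd − mean_w(fd)|)` computed with two uniform filters.
  It is cheap, vectorised, and shares the property that matters: it is
  near `sd(fd) × √(2/π)` under uniform coverage (well below the 0.3 × mean
  cutoff at ≥ 10×) and spikes at coverage steps caused by misassembly.
* **Edge exclusion.** The first/last insert-mean bases of each sequence are
  excluded from fragment-coverage flags (`low_fc`, `fcd_err`,
  `coll_repeat`): fragments cannot fully cover sequence ends, so depth
  there is structurally depressed and would always flag.
* **Relative thresholds.** Coverage cutoffs are fractions of the global
  mean, so 10× and 30× libraries behave alike.
* **links counts bases,** not events, consistent with every other flag
  being a percent of bases.
* Mean read depth of zero raises an "insufficient coverage" error; the
  pipeline additionally warns below 10× and refuses below 2×.

## Feature selection

Pearson filter (drop −0.1 < r < 0.1 against the target; zero-variance
columns dropped with a warning), pairwise correlation report (|r| > 0.8
flagged), JMIM greedy ranking, OOB permutation importance, exhaustive
best-subset OLS (sizes 1–6).

* **Discretisation for mutual information:** equal-frequency binning,
  10 bins (configurable); columns with ≤ 10 distinct values keep their own
  levels. JMIM adds the candidate maximising the minimum joint MI
  I(X, X_s; Y) over already-selected features; ties break by input order.
* **%IncMSE** replays each tree's bootstrap to find its out-of-bag rows and
  measures the percent OOB-MSE increase after permuting one column,
  averaged over trees and repetitions — the forest-native importance, not
  a whole-model permutation score.
* **Sign-contradiction rule.** The final subset is the highest-R² subset in
  which no OLS coefficient sign contradicts the feature's marginal
  correlation sign. This formalises the observed failure mode where a
  metric that correlates negatively with quality receives a positive
  weight under multicollinearity; the exclusion is automatic but reported
  (`sign_excluded`).

## Model families and tuning

All families share one seeded 80/20 split (|train| = round(0.8 n)).
Hyperparameters minimise cross-validated RMSE:

| family | CV | grid |
|---|---|---|
| glm (OLS) | 10-fold × 10 repeats | — |
| elastic net | 10-fold | l1_ratio 0…1 step 0.1 × λ ∈ 10^[−4,1] (standardised) |
| knn | 10-fold × 5 repeats | odd k 3…21 (standardised) |
| rf | 10-fold | 500 trees; mtry ∈ {2, 4, 6} |
| svm linear / poly | 5-fold | C ∈ {0.25, 0.5, 1, 2, 4}; degree ∈ {2, 3} (standardised) |

Test R² is reported both as the squared Pearson correlation of predicted vs
observed (the line-of-best-fit convention) and as 1 − SS_res/SS_tot;
selection uses RMSE with ties broken by the former. Constant predictions
report R² = 0 with a warning. The winning family is refitted on all rows;
models persist as a directory (metadata JSON + joblib estimator) and a
load round trip reproduces predictions bit-for-bit. All randomness (split,
folds, bootstraps, permutations) descends from one seed recorded in the
model metadata.

## Simulators

`mutate_assembly` injects SNPs (uniform random different base), indels
(geometric(0.5) sizes capped at 50 bp), CNV gains/losses (exponential
lengths, mean 1 kbp) and gaps (segments overwritten with N, exponential
lengths, mean 500 bp), never starting inside existing gap runs, with a full
truth log. `simulate_reads` draws fragments at uniform positions with
normal(450, 45) lengths, resampling N-containing fragments up to 10 times;
mates are the fragment ends (which end is mate 1 is randomised); per-base
errors are Bernoulli. Read count = coverage × length / (2 × read length).

`generate_training_set` emulates the training construction: per synthetic
genome, a degradation gradient of five profiles (single-base error rates
0/5/10/15/20 % with small matching indel, gap and fragmentation loads);
reads are simulated from the *pre-degradation* reference and mapped to the
degraded copy, so mapping metrics see the injected errors exactly as real
reads see assembly errors; PMB plus both scaling rounds supply the target.
Defaults are 20 genomes × 5 levels at 25 kbp — sizes chosen so a full table
builds in well under a minute while leaving > 50 insert lengths per
sequence; the cheap `synthetic_metrics_table` (parametric metric vectors
with a saturating mapping-collapse response and Gaussian score noise,
sd 5) serves model benchmarking at larger n without any sequence work.

What the simulators do **not** emulate — and hence what passing tests do
not establish about real data: sequencer error profiles and quality
strings, GC/coverage bias, true repeat structure (uniform-random DNA is
nearly repeat-free, so `coll_repeat` and multi-mapping stress are mild),
heterozygosity, and contamination. The end-to-end recovery results
(held-out R² ≥ 0.8, monotone score collapse with its steepest drop between
the 10 % and 15 % error levels) demonstrate that the pipeline's metrics
carry the quality signal and the model can read it — not that the shipped
defaults equal the published mammalian model, which was trained on real
chromosome-scale data.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open throughout; exported intervals are
BED-convention. Lowercase bases are uppercased (soft-masking ignored); gap
runs are maximal N/n runs; contigs split at gap runs ≥ 1 N by default
(configurable). N50/N90 use the standard descending-cumulative definition
(single-piece assembly ⇒ normN50 = 100); both scaffold- and contig-level
values are emitted, scaffold `normN50` feeds the model. Empty assemblies,
empty length lists, zero reference length, unknown model families, missing
metric columns and trains smaller than 2 × folds all raise immediately with
the offending name in the message. Scores above 100 are legal outputs
(cleaner than the best training chromosome); scaling factors clip at 0.

## Known limitations

* Whole-assembly difference counting assumes query scaffolds are in
  reference order; use an external aligner for rearranged assemblies.
* The perfect-metric vector yields a perfect score for *any* sized piece of
  an assembly; per-sequence output always states the granularity so a
  perfect 10 kbp contig is not mistaken for a perfect genome.
* The exact-seed mapper is built for the 10–30× short-read regime at desk
  scale; chromosome-scale mammalian inputs want a production mapper via
  the SAM/BAM path.
* Long-read (PacBio/Nanopore) metrics are out of scope.
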