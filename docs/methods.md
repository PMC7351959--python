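# Methods

## Scope and data model

`sinktrack` analyses ASV count tables (taxa x samples, non-negative
integers) with a companion mapping file assigning each sample a role
(source, sink, or negative control), an environment label, and — for sinks
— an ordered processing-line position. Tables enter pre-classified: no
sequence-level processing (denoising, chimera removal, taxonomy
assignment) happens here. Column sums are treated as library sizes and
recomputed on demand, never cached.

## Table cleaning

Two rules run in a fixed order, once, with no iteration to a fixpoint:

1. **Low-yield filter** — samples with fewer than 200 reads are dropped
   first; then taxa whose total count *over the remaining samples* is below
   5 are dropped. Filtering taxa after sample removal means a taxon carried
   only by discarded shallow samples is also discarded; the operation is
   idempotent.
2. **Prevalence decontamination** — for each taxon a 2x2 presence/absence
   table (control vs true sample) is scored with a one-sided Fisher exact
   test for the alternative "more prevalent in controls". Taxa with score
   below the threshold (default 0.5) *and* strictly higher control
   prevalence are removed. The exact test is well defined at the very
   small blank counts typical of these studies (2–3 controls), and the
   direction gate guarantees an abundant genuine taxon can never be
   flagged merely for ubiquity. Tests verify the score against brute-force
   hypergeometric tail enumeration.

## Rarefaction

Rarefaction is classic without-replacement subsampling: each sample with
library size >= depth is replaced by a uniform draw of exactly `depth`
reads (`numpy`'s multivariate hypergeometric); shallower samples are
dropped and logged, never resampled with replacement. Every sample draws
from its own random substream, derived from the master seed plus a stable
hash of (sample id, depth), so adding or removing other samples never
perturbs a sample's draw.

## Source attribution

The sampler implements the standard Bayesian source-tracking mixture: V
known source environments (source samples are summed per environment) plus
one latent Unknown environment per sink. Known-source taxon profiles are
fixed smoothed empirical distributions,
phi[v, t] = (m_tv + a1) / (sum_t m_tv + T a1); the Unknown profile is
learned from the sink's own reads through its Dirichlet(a2) posterior
counts; a symmetric Dirichlet(beta) prior covers the (V+1)-way environment
mixture. Each sink is processed independently: reads are expanded
taxon-id-sorted, initialized uniformly at random over V+1 environments,
and swept by a collapsed Gibbs kernel (numba-compiled; a pure-Python
conditional-distribution function and an exact enumeration oracle provide
independent cross-checks).

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| alpha1 | 0.001 | pseudocount smoothing known-source profiles |
| alpha2 | 0.1 | pseudocount for the Unknown source's taxon distribution |
| beta | 10 | symmetric prior count per environment on the sink mixture |
| restarts | 10 | independent chains per sink |
| burnin_passes | 100 | sweeps discarded per chain |
| draws_per_restart / delay_passes | 10 / 10 | retained draws and their spacing |

These are the canonical defaults of the widely used reference
implementation of this model; every one is configurable. Source profiles
are fixed by default; per-restart Dirichlet resampling of profiles
(`resample_source_profiles`) is available because implementations differ
here, but stays off so the sampler can be validated against the
enumeration oracle, which assumes fixed profiles.

Reported proportions are means over all retained draws (restarts x
draws_per_restart), with their standard deviation; per-taxon assignment
tallies are means of the per-draw read assignment counts, so proportions
equal assignment column sums divided by sink depth by construction. Sinks
are analysed at whatever depth they arrive with — depth manipulation
belongs to the depth-robustness experiment, not the sampler.

Numerical notes: the shared conditional denominator (n - 1 + (V+1) beta)
cancels inside the kernel and is kept only in the exported
conditional-distribution function; smoothing makes every conditional
strictly positive, so no zero-probability states arise; downstream argmax
ties break toward the lexicographically smallest environment label.

## Summaries

The flow table averages sink proportions per processing-line position and
scales to percent (columns sum to 100). The genus x source matrix sums
mean assigned read counts over sinks per (genus, source), pools
non-relevant genera into "Other", and normalizes per genus (columns sum
to 1; row normalization is available behind a flag). Genus columns with
zero assigned reads are dropped with a warning rather than emitted as NaN.
Genus ordering uses average-linkage hierarchical clustering on Euclidean
distances between source-contribution vectors; linkage and metric are
configurable since the choice is conventional. Contributions are
unweighted read fractions; weighting by absolute abundance (e.g. qPCR
cell-equivalents) is deliberately not folded in.

## Depth-robustness experiment

A reference attribution runs once at full depth. For each depth in the
ladder (default 7712 / 5000 / 1000 / 500 / 200) and each replicate (3 per
depth, 10 at the smallest, where variance is expected to be largest), the
whole table is rarefied on a fresh substream and re-attributed with the
*same* Gibbs configuration as the reference — so at depth = full library
size the comparison is exactly zero/one/100, and replicates differ only
through rarefaction randomness. Four statistics compare each run to the
reference:

- **mean squared difference** of the proportion cells (cellwise, averaged
  over all sinks x environments; a per-sink or aggregate variant would be
  defensible — the cellwise choice is the strictest);
- **Spearman rho** of the flattened proportion cells (average-rank ties);
- **hit ratio** — percent of sinks whose top-ranked environment (Unknown
  eligible, ties to the smallest label) matches the reference's; a top-k
  variant exists;
- **unknown-rate difference** — per-sink |est - ref| of the Unknown
  proportion, in percent. "Unknown classification rate" is read-level
  (the Unknown share of the attribution), not an ASV tally.

Replicate values per depth are screened with Shapiro–Wilk (per group) and
Levene (across groups), then compared with Kruskal–Wallis and a Dunn
post-hoc z test (pooled ranks, tie-corrected variance) under
Benjamini–Hochberg adjustment. Undefined cases (constant groups, fewer
than 3 replicates) are reported explicitly as gaps, never silently
dropped.

## Diversity and bench counts

Alpha diversity (observed taxa, Shannon with natural log, Simpson
1 - sum p^2) is computed after rarefying all samples to the minimum
library size so richness is comparable. Bray–Curtis uses raw counts,
BC(x,y) = sum|x_i - y_i| / sum(x_i + y_i). Grouped comparisons gate on
Shapiro–Wilk at alpha = 0.05 (the conventional level; only the test, not
the level, is standard in the source protocols) to choose a paired t-test
vs Wilcoxon signed-rank, BH-adjusted over the comparison family; groups
under 3 values fall back to Wilcoxon with a warning. Bacterial cell
equivalents divide qPCR 16S gene copies by 4, the database-derived average
rRNA operon copy number. BCE-vs-plate-count correlations are Spearman
within each sampling position, requiring at least 3 complete pairs.

## Synthetic facility generator

The generator emulates the structure of a processing-line surveillance
campaign at the ASV-count level (no reads, no error models):

- **15 source environments** along the line (anal swab, skin, singeing
  oven, polishing equipment, gloves, knives, railing, walls, ...), each
  with 5 replicate swabs by default; profiles are symmetric
  Dirichlet(0.1) draws over the shared taxon pool — sparse,
  location-specific communities.
- **Sinks** at 6 ordered positions (Sticking ... Truck), 12 per position
  by default (one per tracked carcass). Each sink mixes 3 randomly chosen
  source profiles (Dirichlet(1) weights) plus an unknown community whose
  weight is uniform on [0.1, 0.4]; fixed weight matrices can be supplied
  and are recorded verbatim. The unknown community places half its mass
  on taxa absent from every source (identifiable) and half overlapping
  (the hard case).
- **Depths** are log-uniform on [200, 30000] by default, mirroring the
  wide spread of real campaigns; separate source/sink ranges allow
  experiment-specific control (e.g. pinning sinks to 5000 for recovery
  runs, or >= 7712 so a rarefaction ladder retains every sample).
- **Negative controls** draw from an even Dirichlet(5) contaminant
  profile over reserved taxa, modelling reagent contaminants that recur
  across blanks; optional low-weight spiking pushes contaminants into a
  fraction of true samples so decontamination has real work, and optional
  cross-talk background can be mixed into blanks. With spiking off, the
  prevalence filter recovers the planted set exactly.
- **Taxonomy**: taxa are partitioned into synthetic genera with
  geometric-ish size distribution (a few dominant genera, many rare), so
  genus-level summaries are testable.

All randomness flows through named substreams of one master seed; the
emitted truth object (profiles, mixtures, contaminant set, depths) is
sufficient to recompute every expected value used in tests.

What the generator does *not* emulate: real communities' very long
abundance tails and thousands-of-ASV richness, compositional correlations
between neighbouring positions, PCR/sequencing error, or batch effects.
Consequently, passing recovery tests shows the inference machinery is
correct under the stated generative assumptions, not that attribution on
real facility data reaches the same accuracy. One knock-on effect is
documented and accepted: with Dirichlet(0.1) profiles even 200-read
sources remain well covered, so at low depth the beta-prior's shrinkage
toward the uniform mixture outweighs source-coverage loss and the
estimated unknown rate *declines* slightly with shallower data, whereas on
real, much richer communities the unknown rate rises sharply at low
depth. The depth experiment's other signatures (hit ratio falling,
squared differences growing, rank correlation decaying at shallow depth)
reproduce robustly.

## Problem sizes

Validation runs use a scaled facility: 15 source environments (2–5 swabs
each), 12 sinks (2 per position), 200–300 taxa, sink depths 5000–8000,
and the full default depth ladder. These sizes keep the complete suite
and the acceptance script at a few minutes on one CPU while leaving every
qualitative contrast (deep vs shallow, known vs unknown, contaminated vs
clean) intact; they are stated here so results are read at the scale they
were computed.

## Known limitations

- The enumeration oracle is exponential in sink depth and only validates
  tiny instances; correctness at scale rests on those plus invariant and
  recovery tests.
- Leave-one-out source-vs-source attribution and variational/EM
  alternatives are out of scope; the sampler is Gibbs-only.
- Attribution runs at ASV level; genus-level results are derived
  afterwards from assignment tallies, since collapsing before inference
  would discard the resolution that motivates full-length 16S data.
- The Dunn test uses the large-sample normal approximation; at 3
  replicates per depth its p-values are indicative, which matches how
  such screens are used in practice.
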