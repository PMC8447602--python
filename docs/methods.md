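# Methods

## Overview

`apmskit` implements the quantitative workflow of multiplexed
affinity-purification LFQ proteomics: calling the interactors of tagged
bait proteins against the shared background of non-specific binders,
quantifying activation-time-course changes of interactions and
posttranslational-modification (PTM) sites on a normalized-ratio scale,
clustering co-regulated time profiles, and assembling the multi-bait
interaction network.  A synthetic-data generator reproduces the
statistical structure these procedures assume, so every stage is
benchmarked against a known truth table.

## Interactor calling

### Model

Each pull-down measures the bait's replicates on top of a background
binder population common to all pull-downs.  For a protein *p* and bait
*b*, let x be the log2 LFQ intensities of *p* in *b*'s samples and y its
intensities in the *complement* — all other samples in *b*'s background
control group.  The statistic is the two-sided two-sample Student's t with
pooled variance:

    t = (mean(x) − mean(y)) / sqrt(s_p² (1/n₁ + 1/n₂)),
    s_p² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2).

A protein is a significant interactor iff its permutation q-value is below
the FDR threshold (default 0.01), its linear fold enrichment
2^(mean(x)−mean(y)) exceeds the enrichment threshold (default 2; 4 for
stringent network figures), and it is *testable* — at least `min_valid`
originally-observed (non-imputed) intensities in the bait group (default
10).  Imputed cells are pseudo-data; requiring observed values in the bait
group prevents calling interactors out of imputation noise.  The pooled
(not Welch) t is the default because it is the two-sample default of the
analysis environment this workflow models; Welch can be selected by
computing the statistic externally.  No s0 variance moderation is applied
(s0 = 0): the fold-enrichment cutoff plays that role here.

### Preprocessing

1. Remove decoy (reverse), contaminant and only-identified-by-site rows;
   require ≥ 2 razor+unique peptides.
2. log2-transform; raw 0 = not quantified becomes missing.
3. Keep proteins quantified in strictly more than 60% of the replicates of
   at least one bait cell line (3/5 = 60% exactly is removed).
4. Impute each remaining missing cell, per sample, from
   Normal(m − 1.8·s, (0.3·s)²) where m and s are that sample's observed
   mean and standard deviation — a narrow Gaussian placed just below the
   per-sample detection limit, encoding the missing-not-at-random origin of
   LFQ dropout.  Width 0.3 and downshift 1.8 are the standard parameters of
   this procedure; the acceptance benchmark verifies the realised values on
   10⁵ draws.  Imputation is per-sample because detection limits differ
   between runs, and is done once on the full filtered matrix.

### Control groups

Samples are clustered by average-linkage hierarchical clustering on
distance 1 − Pearson r between their intensity profiles (pairwise-complete
over observed cells; ≥ 10 shared observations per pair required).  The
tree is cut into `n_groups` clusters; `auto` maximises the mean silhouette
over k = 2..min(6, #baits − 1).  Each bait's replicates are then assigned
as a block to the group holding their majority, so no bait is split across
control groups; singleton groups are rejected.  The number of groups is a
user decision in real designs (batches of pull-downs processed together
correlate strongly); the default synthetic design uses one group.

### Permutation FDR

For each of `n_permutations` (default 250) random relabelings of the
group's samples that preserve the bait-group size, |t| is recomputed for
every testable protein.  For the cutoff c = |t_i| of each observed protein,

    q_i = min(1, mean over permutations of #{|t_perm| ≥ c} / #{|t_obs| ≥ c}),

then q is made monotone non-increasing in |t| by a step-up pass (running
minimum from the least significant protein toward the largest |t|, as in
Benjamini–Hochberg enforcement).  Two details:

* Relabelings that reproduce the observed partition (the observed group or
  its mirror when group sizes are equal) are excluded — they carry no null
  information and would floor the attainable q at 2/n_perm on small
  designs.
* When the number of remaining distinct relabelings fits within the
  permutation budget they are enumerated exhaustively, making the estimate
  exact; a 3-vs-3 design is verified against brute-force enumeration in
  the tests.

Ties in ranking are broken by ascending q, then descending difference,
then protein id, so outputs are bit-reproducible.

### Whole-proteome comparisons

The same machinery with the whole-proteome defaults: FDR < 0.05,
enrichment > 2, minimum 2 valid values in the first group.

## Time-course dynamics

Ratios, not raw intensities, are analysed:

* PPI: normalized prey = prey LFQ / bait LFQ, per sample, on the linear
  scale.  This removes loading artifacts — scaling a whole sample scales
  bait and preys alike, and the tests verify this scale equivariance
  exactly.  A sample in which the bait itself was not quantified yields
  missing ratios for all preys in that sample.
* PTM: site intensity / carrier protein intensity, per sample.  Peptide
  rows mapping to one (protein, modification, position) site are summed
  before normalization.  A site enters the analysis only if it has valid
  ratios in ≥ 3 replicates of ≥ 1 time point.  **No imputation is ever
  applied on the PTM branch** — occupancy ratios of sparsely observed
  sites would be dominated by imputation noise.

Per activated time point, each feature is compared to the untreated
(time 0) condition with a two-sided Student's t-test at per-test α = 0.05,
with no multiplicity correction across time points or features — the
workflow screens candidates rather than certifying them, and the heatmap
asterisk convention marks "significant in ≥ 1 time point".  Tests run on
log2 ratios by default (symmetric around no-change); raw-ratio testing is
available via `log_ratios=False`.

## Co-regulation clustering

Features with ≥ 70% valid values across the samples feeding the profile
are reduced to one value per time point (median over replicates), then
z-scored across time points (population sd, so mean 0 / sd 1 exactly;
constant profiles are dropped as their z-score is undefined).  The order
is normalize → per-time-point median → z-score.  Profiles are clustered by
average-linkage hierarchical clustering on 1 − Pearson r and the tree cut
into k clusters (default 7, a display-level choice; k is a user decision).
Labels are deterministic: ordered by descending cluster size, ties by
earliest peak time.  Cluster summaries report the per-time-point median of
member z-profiles, a bootstrap 95% percentile band of that median (1,000
resamples, seeded), and a lowess curve (tricube-weighted local linear
regression, span 0.75) through the member points.

## Network assembly

One node per distinct protein over all baits' significant calls; one edge
per significant (bait, prey) pair carrying the log2 difference and q.  A
prey called by several baits appears once with degree ≥ 2, connecting the
pull-down experiments.  Prey novelty is annotated from a user-supplied
offline two-column list of known interactions, matched per unordered
(bait, prey) pair; no live database queries, so builds are hermetic.
Exports: GraphML and a plain edge-list TSV.

## Synthetic data generator

What it emulates, and the defaults (all log2 scale unless noted):

| parameter | default | meaning |
|---|---|---|
| n_baits × replicates | 20 × 4 | pull-down design |
| n_background | 2000 | shared non-specific binders |
| background_mean / sd | 24 / 2 | latent log2 LFQ level per protein |
| interactors_per_bait | 15 | spiked true interactors |
| log2_effect | 3 | mean bait-vs-complement enrichment (8-fold) |
| bait_self_effect | 6 | bait-row self-enrichment |
| replicate_sd | 0.3 | per-cell log2 noise |
| mnar_midpoint / slope | 21 / 0.8 | logistic dropout: P = σ((midpoint − log2 x)·slope) |
| timepoints | 0/5/15/30 min | activation time course |
| dynamic_amplitude | 1.5 | peak log2 modulation of dynamic features |

Background proteins share one latent level across all samples, which
induces the > 0.9 inter-sample Pearson correlations typical of replicated
pull-down batches (asserted in the tests).  Dynamic features follow
multiplicative trajectories: `early_up` peaks at the first activated time
point then decays, `late_up` rises monotonically, `down` falls, `flat` is
constant.  PTM sites are generated as carrier protein intensity ×
occupancy trajectory × noise, so protein-normalized ratios trace the
occupancy.

What it does **not** emulate: peptide-level identification noise, shared
peptides between protein groups, ratio compression, batch effects beyond
the shared background, co-complex correlation between preys, and
non-logistic missingness.  Passing benchmarks therefore demonstrate the
statistical machinery under the assumed model, not performance on any
particular real dataset.

## Benchmarks and problem sizes

The acceptance benchmark runs the full calling workflow on 20 datasets at
the default design (2,320 proteins × 80 samples each) and averages the
empirical false-discovery proportion; with `min_valid = 3` of 4 bait
replicates, FDP stays at ~0 (≤ 0.01) while recall at log2 effect 3 is
~1.0 without dropout.  `min_valid = 3` is the 4-replicate analogue of the
default 10: the default presumes bait groups pooled over several
conditions/time points (e.g. 16 samples), and demanding 10 observed values
from 4 replicates would render everything untestable.

### Known limitation: power under MNAR dropout at few replicates

With dropout on, recall at 4 replicates drops to ~0.6 while the FDP bound
still holds.  The cause is instructive: an abundant background protein
with a handful of dropout cells gets those cells imputed ~6 log2 units
below its level; a permutation that concentrates these outlier cells in
the small pseudo-bait group produces a very large |t|.  Pooled two-sided
permutation counting then inflates the estimated null tail, which raises q
conservatively at exactly the cutoffs where true interactors sit.  Larger
bait groups (the regime the min_valid = 10 default reflects) dilute the
effect and restore separation.  Practical advice: with ≤ 4 replicates per
bait, prefer larger pooled bait groups, or raise the enrichment threshold
rather than relying on q alone.

## Numerical choices and degenerate inputs

* Zero pooled variance: t = 0, p = 1 when the means agree; ±∞, p = 0
  otherwise (infinite observed |t| sorts above any finite cutoff).
* Constant sample profiles in correlation: r = 1 if identical, else 0.
* All randomness flows through explicit `numpy.random.default_rng` seeds;
  the pipeline fans one global seed out to per-stage child seeds by a
  fixed affine derivation, so a run manifest reproduces every table
  bit-exactly.
* Floats are serialized with `%.17g`, making TSV round-trips bit-exact.
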