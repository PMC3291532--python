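# Methods

## Copying model

Each recipient haplotype is modelled as a mosaic of donor haplotypes under
a Li–Stephens hidden Markov model. Hidden state: the donor currently
copied, uniform initial distribution within each region. Transition across
a map interval of `g` Morgans: stay with probability `exp(-rho_eff * g)`,
otherwise re-choose uniformly among all `k` donors (the re-choice may land
on the same donor), with `rho_eff = rho * ne_scale`. Emission: `1 - mu` on
an allele match, `mu` on a mismatch. Regions are unlinked and treated as
independent chains. The forward recursion is rescaled at every site and the
log-likelihood accumulated from the scaling constants, so likelihoods are
exact in log space for panels of any size; the batched implementation
(`copying._fb_batch`) processes all recipients simultaneously and is
verified in the tests to reproduce the per-recipient reference recursion
exactly.

EM updates the two global scalars only. The expected number of re-choice
events per interval (from the forward-backward joint transition
probabilities, decomposed into stay and jump routes) feeds a
one-dimensional numeric M-step for `rho` (bounded search on `log rho`,
maximising the expected complete-data transition log-likelihood); `mu` is
the expected mismatch posterior mass divided by the total painted sites,
clamped to `[1e-8, 0.5]`. `ne_scale` is never EM-updated: it is fixed per
run and selected by `ne_grid_search` as the grid value maximising the total
fitted log-likelihood, mirroring the separation between a fixed map-scaling
grid and within-run EM. EM runs a fixed number of iterations (default 100)
rather than to a convergence tolerance; the trace is recorded and checked
to be non-decreasing.

Two summaries are exposed per donor: occupancy (mean site-wise posterior,
the default for population-level copy matrices) and the expected number of
maximal copied segments (initial-state posterior per region plus expected
switches into the donor). Both are reported because "closest relative"
proportions can be defined from either; occupancy is smoother at these
region sizes, where few breakpoints are observed. Copying from the other
haplotype of the same individual is excluded by default; the exclusion is
structural (those donors are removed from the state space), so the
corresponding occupancy entries are exact zeros. Ties in any argmax
painting are broken toward the lowest donor index. Posterior mosaic samples
(`sample_fragment_assignments`) are drawn by backward sampling from the
scaled forward matrices; per region and haplotype the empirical population
fractions converge to the marginal posterior population mass.

Population aggregation sums each recipient haplotype's occupancy by donor
population, averages the two haplotypes of an individual, then averages
individuals within a population. Known hybrids carry the label `hybrid`;
they are painted like everyone else, but can be excluded from the donor
side (with row renormalisation) since "hybrid" is not a population of
origin.

## F_ST

Hudson's estimator on sample allele frequencies with finite-sample
correction, combined across sites as a ratio of sums (ratio of averages) —
the standard combination for this estimator family; sites monomorphic
across the pooled pair, or with fewer than two called chromosomes in either
population, are skipped. Allele counts come from diploid genotypes; the
estimator is invariant to which allele is labelled reference. Confidence
intervals use a delete-one-block jackknife over regions (the natural block
given unlinked clusters) on the ratio statistic, with a normal-quantile
interval; a t-interval would differ negligibly at 20+ blocks and the
z-form keeps the interval symmetric around the point estimate.

## PCA and hybrid scoring

Missing calls are imputed with the site mean, the matrix is mean-centred
and not variance-scaled, and scores come from a standard truncated PCA.
Reference clusters are either the provided labels (hybrids excluded from
centroid construction) or connected components under a score-space distance
threshold (default: three times the median nearest-neighbour distance).
Hybrid intermediacy is geometric: 1 at the midpoint of the two nearest
centroids, 0 at either centroid, clipped below at 0. The planted-hybrid
test asserts the projection of an F1 lies strictly between the parental
centroid projections on PC1.

## Quality control

The exact conditional Hardy-Weinberg test enumerates all heterozygote
counts compatible with the observed allele counts and sums the
probabilities of configurations no more probable than the observed one
(two-sided by probability ordering). The filter cascade removes
visually flagged sites, sites with more than `max_no_call` missing calls
(default 0: any no-call), and sites failing HWE within any labelled
population at `alpha` (default 0.001, a conventional "strong departure"
threshold); a site failing several filters is removed once and listed under
every reason. Missing genotypes are excluded site-wise from all frequency
and HWE computations; nothing is imputed outside PCA.

## Synthetic data generator

The generator emulates the study design end to end so that every stage has
a planted truth:

* **Demography.** Discrete-generation Wright-Fisher on pools of `2N`
  haplotypes, founded from standing variation with a drift-like (1/x)
  ancestral frequency spectrum on [0.05, 0.95]. One ancestral pool splits
  sequentially (caterpillar topology) at strictly decreasing times; every
  pool drifts independently to the present. Under pure drift, pairwise
  Hudson F_ST ≈ `1 - exp(-t / 2N)`; the defaults (N = 50 diploids, splits
  at 20 and 15 generations) put the three pairwise values near 0.13-0.18,
  the regime the pipeline targets. The two-population calibration against
  the closed form is part of the acceptance checks.
* **Genome.** 22 unlinked regions of clustered SNPs (default 35 per
  region), uniform within-region map distance totalling 0.001 Morgans per
  region — short enough that few copying breakpoints fall inside a region,
  as in real clustered-SNP assays. Between regions recombination is free.
  Monomorphic sites are dropped after sampling.
* **Hybrids.** F1 individuals take one haplotype from an unused parent in
  each of two populations; truth paths mark each haplotype with its
  parental population.
* **Uniparental locus.** Each individual carries a non-recombining lineage
  label equal to its population, relabelled to a random other population
  with the configured discordance probability — the single-locus
  misclassification scenario.
* **Ascertainment.** SNP "discovery" keeps the sites heterozygous in one
  chosen individual, reproducing single-genome ascertainment and its MAF
  spectrum shift.
* **Planted mosaics.** `simulate_copying_mosaics` generates recipients
  under the copying process itself with a known switch rate and miscopy
  probability, giving an exact target for EM parameter recovery.

What the generator does **not** emulate: mutation during the drift phase is
off by default (negligible over tens of generations), there is no gene
flow after splits, no genotyping error model beyond planted no-calls, and
haplotypes are taken as known rather than statistically phased. Passing
tests therefore demonstrate correctness of the inference machinery under a
clean drift-divergence model, not robustness to phasing error or complex
demography.

## Resampling harness

Cross-dataset comparisons are confounded by SNP ascertainment; the harness
equalises it empirically. A template records, per region, the SNP count in
five minor-allele-frequency bins ((0,0.1] ... (0.4,0.5]). Each replicate
draws individuals per population, then pairs every template region with a
random panel region holding enough candidate SNPs (necessary because
single-individual ascertainment can empty a region), then samples SNPs
without replacement to reproduce the template histogram exactly; when a bin
is underfilled the shortfall is borrowed from the nearest non-empty bin and
logged. Copying (at a reduced, configurable EM budget — the full 100
iterations per replicate would be wasteful since only aggregate copy
proportions are consumed) and F_ST are computed per replicate; summaries
are empirical central 95% intervals (type-7 quantiles) and paired
exceedance counts. Per-replicate generators derive from
`SeedSequence((seed, replicate_index))`, so any replicate is reproducible
in isolation.

## Panel selection

Training/test splitting is a per-population random half split (odd counts
round up to training), hybrids excluded. Single-SNP assignment uses
Hardy-Weinberg genotype probabilities under training-sample allele
frequencies floored at `1/(2n+1)` (no genotype gets probability zero);
exact ties and missing genotypes are "unassigned", which counts as an
error. SNPs are ranked by training assignment accuracy, ties broken by the
larger maximum pairwise frequency differential and then site order, and
selected greedily with at most one SNP per region, so panel SNPs are
unlinked by construction and the multi-SNP rule (sum of per-SNP log
genotype probabilities, missing SNPs skipped) is a sound naive-Bayes
product. Held-out evaluation refuses any overlap with the training ids.
The full-SNP-set baseline is nearest-centroid assignment on mean training
genotype vectors. A caveat documented from the synthetic experiments: with
neutrally drifted standing variation at F_ST ≈ 0.15, a 10-SNP panel
typically classifies ~90-96% of held-out samples while the full-data
centroid is at ~100%, so small panels approach but do not always equal the
full-data discrimination; assay-designed SNP pools enriched for
informativeness close this gap.

## Numerical and design choices

* Genotypes are int8 with -1 for missing; haplotypes 0/1.
* VCF coordinates are 1-based inclusive, BED half-open 0-based; conversions
  happen only in the IO layer (`pysam` reads and writes the VCF).
* The rho M-step groups equal interval lengths before the bounded search;
  with no expected jumps, rho collapses to its lower bound 1e-6.
* `CopyParams` bounds: `0 ≤ mu ≤ 0.5`, `rho ≥ 0`, `ne_scale > 0`.
* Degenerate inputs error explicitly: empty donor sets, negative map
  distances, single-block jackknives, monomorphic PCA input, discovery
  individuals without heterozygous sites, candidate pools smaller than a
  template.
* Problem sizes in the test suite and acceptance script (for example,
  10-12 individuals per population and 10-18 regions in seed-replicated
  checks, the full 18/22/35 design for single end-to-end fits) were chosen
  to keep seed-replication practical on a single CPU while staying in the
  regime the defaults define; they are stated in the tests themselves.
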