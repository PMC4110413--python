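# Methods

## Data model

Collections are inbred single-seed-descent lines, treated as effectively
homozygous: one allele per accession per locus. Allele codes are positive
integers (fragment sizes in bp); two reserved codes exist, `0` for a NULL
allele and `-9` for missing. A NULL allele is a heritable allele state (a
primer-site mutation yields no PCR product), distinct from missing data,
and every diversity computation counts it as an ordinary allele. Missing
calls are excluded from allele-frequency denominators, from pairwise
distances (pairwise-complete loci) and from the admixture likelihood.

Chromosome labels concatenate tokens of the form digit + genome letters
("3A", "7BD5B"); a marker is genome-specific iff the set of letters across
all tokens has size one. Some multi-genome markers are conventionally
attributed to a single genome in genome-partition analyses; this is
exposed as an explicit `genome_override` mapping rather than a parsing
rule.

## Marker QC

A no-product reaction is scored NULL only when (a) there is no product,
(b) the accession's success rate over the *other* loci is at least
`dna_quality_min`, and (c) the locus's overall no-product fraction is
below `locus_missing_threshold` (default 0.05). "Good DNA" is not a number
one can read off a scoring sheet, so rule (b) operationalizes it as the
cross-locus success rate with a default of 0.80; both thresholds are
configuration. Loci with strictly more than 20 % missing data are
excluded. Sister-pair divergence counts loci where both members are
non-missing and differ; missing loci leave both numerator and denominator.

## Diversity indices

Standard textbook forms are used: Nei's gene diversity `1 − Σpᵢ²`, PIC
`1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²`, Shannon–Weaver `−Σpᵢ ln pᵢ` (natural log),
and hypergeometric rarefaction `Σᵢ [1 − C(n−nᵢ, g)/C(n, g)]` computed with
log-gamma binomials so large allele counts cannot overflow. A "rare"
allele is one with frequency below 0.05 (configurable; no universal
definition exists). The rarefaction size `g` defaults to the smallest
non-missing sample size over the included loci. No small-sample
`n/(n−1)` correction is applied to Nei's diversity by default (flag
available): the reference analyses do not use one.

Phenotype diversity bins the pooled (all-trial) trait range into 12
equal-width classes — "classes of similar size" is read as equal interval
width; an equal-count (quantile) binning is available behind a flag — and
applies the Shannon–Weaver form to per-trial class frequencies. A
constant trait yields 0 with a warning rather than an error.

Genome-partitioned diversity averages an index over a genome's
genome-specific loci, and additionally over seeded random subsets of 8
loci per genome, which makes the comparison across genomes insensitive to
unequal marker counts.

## Admixture model and inference

The model is the classic no-linkage admixture model for haploid data:
`q_i ~ Dirichlet(α)` ancestry proportions over K clusters,
`p_kl ~ Dirichlet(λ)` allele frequencies, origins `Z_il ~ q_i`, observed
allele `~ p_{Z_il, l}`. One allele copy per locus is modelled because the
lines are inbred; duplicating rows to fake diploidy would only inflate
apparent homozygosity (the diploid export format remains available for
interoperability). α and λ are fixed at 1.0; α is not sampled, which keeps
replicate runs exactly reproducible given a seed. The correlated-
frequencies prior and linkage model are not implemented.

Each Gibbs sweep samples all Z, then Q | Z and P | Z from their Dirichlet
full conditionals (vectorized over all non-missing cells). The per-sweep
data log-likelihood `Σ log Σ_k q_ik p_kl,a` is recorded after burn-in, and
`L_K = mean − var/2` estimates ln P(Data | K), the usual harmonic
penalization of likelihood variance. Reported Q and P are posterior means
over post-burn-in sweeps; within-chain label switching is rare on
structured data at these run lengths and is not corrected within a chain.
Across replicate chains, labels are aligned by the optimal column
assignment (Hungarian algorithm on squared distances between Q columns),
which is exact for the Frobenius criterion.

δK follows Evanno: per replicate second differences of L in K, absolute
value averaged over replicates, divided by the between-replicate sample
standard deviation of L(K). K = 1 runs are always included internally so
δK is defined at K = 2 even when the requested range starts there. δK at
interior K with zero replicate spread is reported undefined (NaN) with a
warning, never infinite.

**Choice of K and "no clear structure".** K* is the interior K maximizing
δK. Because δK is a ratio, noise can produce a nominal peak even for a
homogeneous collection, so the package additionally requires
`mean L(K*) > mean L(1)` before declaring structure; otherwise a single
group is reported rather than forcing a split. The hierarchical analysis
applies the whole procedure to the full collection (sister lines
included), then independently within each level-1 group, truncating the K
range for small groups, and reports the fraction of sister pairs sharing
a level-1 group.

Default run lengths are burn-in 10,000 and 50,000 recorded sweeps. The
test suite and acceptance script use 500 / 2,000 with 3–5 replicates on
collections of 150–220 lines — the model and code paths are identical;
only the Monte Carlo error differs, and the parameter-recovery checks pass
at these lengths.

## Core selection

Objectives: mean per-locus Shannon–Weaver (SWI) or effective-allele number
(NE = `1/Σp_a²`) of the subset, or mean pairwise Modified Rogers /
Cavalli-Sforza & Edwards distance. For homozygous lines both distances
reduce to `sqrt(#differing shared loci / #shared loci)` and coincide; this
is verified by test. The search is steepest-ascent over the single-swap
neighborhood with random restarts (an optional simulated-annealing pass
precedes the ascent behind a flag). The original mixed-replica
metaheuristic of dedicated core-selection software is deliberately not
reproduced: the objective, not the search engine, is the scientific
content, and on every toy instance small enough to enumerate the swap
search reaches the exhaustive optimum. Swap evaluation is incremental —
per-locus allele-count entropy updates for frequency objectives, distance
row-sum updates for distance objectives — so a full neighborhood scan of a
collection-scale problem costs milliseconds.

Retained diversity of a core is `100 × mean per-locus index (core) / mean
(full)` for Nei and Shannon–Weaver (values can exceed 100 % because an
optimized subset balances allele frequencies), plus total and rare allele
counts, which are what a small core actually sacrifices. The reference
analysis chose its final objective by comparing four indices; this package
reproduces that as a report (all four objective values on the final core),
not as a combined objective, since no weighting scheme is defined.

## Synthetic data generator

The generator emulates a genebank landrace collection: ancestral allele
frequencies per locus from a symmetric Dirichlet; population frequencies
from `Dirichlet(ancestral·(1−F)/F)` — the correlated-frequencies F-model,
in which F plays the role of FST (an independent Weir–Cockerham-style
estimator recovers F on generated data, by test). The nested
configuration applies the model twice (top-level split, then subgroup
drift), mirroring the hierarchical analysis. Ancestry is
`q ~ Dirichlet(α)` (one-hot when α = 0); genotypes are drawn cell-wise via
a latent origin; missingness is completely at random per locus at a rate
drawn from a configured range; a locus segregates a NULL allele (one
allele code replaced by the reserved 0) with probability
`null_allele_rate`; sister lines are appended copies with a configured
fraction of loci re-drawn — observed sister divergence is therefore
slightly below the redraw fraction, by the per-locus allele-collision
probability, which tests account for explicitly.

Defaults describe the emulated collection: 826 accessions (plus 28 %
sister lines, giving ~1,057 rows), 45 loci with 3–40 alleles, per-locus
missingness 0–23 %, sister redraw fraction 0.357, weak nested structure
(2 top groups splitting 4 + 5). Differentiation strength is not
documented for the real collection; drift_F defaults to 0.05 ("weak", the
conventional value), with 0.3–0.4 used in recovery tests where the test's
point is identifiability under clear structure. The generator draws i.i.d.
loci (no linkage), no mutation/selection, and MCAR missingness — so
passing recovery tests demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to linkage, genotyping
batch effects or informative missingness in real data.

## Numerical and reproducibility choices

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); replicate-run seeds are derived via
`SeedSequence`. Re-running any stage or the whole pipeline with the same
config is bit-identical, which the pipeline manifest verifies with
SHA-256 checksums per artifact. Argmax group assignment breaks ties
toward the lowest cluster index with a warning. Swap search accepts a move
only if it improves the objective by more than 1e-12, preventing cycling
on ties; the result never scores below its initialization.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at: admixture recovery n=150, L=30, K=1..5,
5 replicates; hierarchical recovery n=200 (+10 % sisters), L=40, K=1..4,
3 replicates; core selection on the full-scale default collection
(~1,057 lines × 42 retained loci, 15 % core, 2 restarts). These sizes were
chosen so each check isolates one property at comfortable statistical
power; the published-table analyses are exact recomputations on the
45-locus reference table shipped with the package.

## Known limitations

* The sampler reports posterior means without within-chain label-switch
  correction; for very weakly structured data at long run lengths the
  mean Q can be smeared toward uniformity.
* `L_K = mean − var/2` is a rough model-evidence surrogate (as in the
  original admixture program); δK inherits its instability when replicate
  spread is tiny.
* Equal-width phenotype binning is sensitive to outliers in the pooled
  range; use the quantile option for heavy-tailed traits.
* The reference diversity table is printed to 1–2 decimals; summary
  statistics recomputed from it carry that rounding (documented
  tolerance: up to 0.1 for 1-decimal columns, 0.01 for 2-decimal
  columns), and two of its published summary cells (mean Shannon–Weaver
  and mean rarefied richness) are not consistent with their own printed
  per-locus values — the recomputed means are reported as computed.
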