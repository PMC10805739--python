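# Methods

`petreldemog` reconstructs the demographic history of a two-colony seabird
system from a reduced-representation SNP panel. The pipeline mirrors a
complete study: SNP quality control, population structure and relatedness,
folded site-frequency spectra (SFS), model-free multi-epoch Ne estimation,
and composite-likelihood comparison of seven two-colony coalescent models.
Because the real genotypes are not bundled, a synthetic-data generator
reproduces the study design so that every stage can be verified by parameter
recovery against known truth.

## Coalescent simulation

Histories are one- or two-deme structured-coalescent models: present-day
diploid sizes, instantaneous resizes, backward-time joins (forward-time
splits), and piecewise-constant asymmetric migration. Within a deme of
diploid size `N` holding `k` lineages, pairs coalesce at rate
`k(k-1)/(4N)` per generation. Migration is parameterized as
`2Nm[s->r]`, the expected number of haploid immigrants entering recipient
`r` per generation (forward direction `s -> r`); backward in time a lineage
in `r` jumps to `s` at rate `2Nm[s->r]/(2N_r)`. Time is in generations;
years enter only at reporting, via the generation time `GT = 18.9` y.
The per-site mutation rate is `mu = 2.89e-9` substitutions/site/generation.

The expected SFS is the Monte-Carlo mean of branch length subtending each
`(i, j)` descendant configuration, normalized over polymorphic entries. The
kernel exploits that a lineage's configuration is fixed for its lifetime, so
each lineage contributes once (death minus birth time) to one SFS cell —
O(1) work per event. An inline xorshift128+ generator supplies event
randomness; all kernels are deterministic given the seed.

### Conditioned-segregating SNPs

Most analyses use SNP panels with no monomorphic sites, so genotypes are
simulated conditioned on segregating. Under infinite sites, a segregating
site falls on a genealogy with probability proportional to that genealogy's
*total* branch length (length-biased sampling): the class law is
`E[l_class]/E[l_total]`, not `E[l_class/l_total]` — the naive
one-mutation-per-genealogy scheme is biased whenever tree length varies,
drastically so for bottleneck histories. The generator therefore simulates a
pool of `pool_factor x n_snps` genealogies (default 8x) and allocates the
`n_snps` mutations across the pool by a multinomial on total lengths. The
marginal distribution of every SNP is exact; SNPs that land on the same
genealogy are correlated, as real SNPs sharing a sequenced tag are. The
pool factor keeps such sharing rare; tests of marginal correctness
standardize by across-seed scatter so this design effect does not masquerade
as bias. An `absolute` mode instead simulates per-tag genealogies with
Poisson(`mu * L_tag * length`) mutations (tags may carry several linked SNPs
or none), which is what DArT-like assays actually produce.

## Synthetic study bundles

`synthdata.generate_study` draws the study design: 31 RDC breeders, 37 RIR
breeders, and 19 light-grounded birds sampled from the RDC deme, default
10,000 SNPs under the fitted "ancient & recent bottlenecks" history (M7,
below). On top of the genotypes it layers what the QC and relatedness stages
must handle: per-locus call-rate/reproducibility/depth metadata (Beta and
log-normal draws tuned so roughly 8% of loci trip each filter), missing
calls, multi-SNP tags, related pairs constructed by Mendelian transmission
(offspring *replace* sampled birds, keeping n fixed), and Z-linked loci
appended on a synthetic Z chromosome (females heterozygous, males
homozygous). Every phase uses an independent child RNG stream, so planting a
relative cannot perturb any other bird's genotypes. A truth log records the
planted structure and the implied assay length (below).

Where the source study prints no value, the truth defaults were fixed once
at field-realistic levels: present colony sizes 100 (RIR) and 160 (RDC)
diploids (census: under a hundred breeding pairs each, RDC the larger);
post-split pre-crash sizes 400 and 800; post-ancient-bottleneck ancestral
size 500 (consistent with "under a thousand birds" through the Holocene).
The recent colony crashes are pinned at 4 generations before present — the
collapses are observationally dated to the last century — and are treated as
constants of the model set, like the migration rates.

The conditioned SNP panel under this history has mean individual
heterozygosity near 0.25, much higher than a real rare-variant-rich panel;
the per-individual heterozygosity QC threshold (default 0.13, a value chosen
for the real panel after plotting) must therefore be set per panel, and the
synthetic analyses use 0.35.

## Quality control

The cascade applies, in order: trimmed-tag removal, one SNP per tag
(uniform random, seeded), individual filters (missingness > 20%,
heterozygosity >= 13%), monomorphic-locus removal, locus metadata bounds
(call rate < 90%, reproducibility < 95%, mean depth < 10x or > 40x — all
strict inequalities), MAF < 0.01, sex-linked markers, and a PCA-regression
outlier scan (per-locus z-scores on the leading component scores,
Mahalanobis distance, genomic-inflation rescaling by the median, chi-square
p-values, Benjamini-Hochberg q < 0.01). Counts telescope step to step.
Sex-linkage is called when the fraction of sexed birds consistent with
Z-linkage (females het, males hom) reaches the concordance threshold
(default 0.95) and both sexes individually lean the right way. Hardy-
Weinberg filtering runs after clustering, within clusters (a pooled
heterozygote deficit can be a pure Wahlund artifact), using an exact
conditional test; a locus is dropped only when significant in every cluster
at the Bonferroni-adjusted level.

## Population structure

Clustering is the discriminant-analysis-of-principal-components recipe:
allele-frequency-scaled PCA (missing calls mean-imputed), K-means over
K = 1..5 with `BIC(K) = n ln(WSS/n) + K ln(n)` and the lowest BIC winning,
then linear discriminant axes fit on the K-means groups with the retained
PC count chosen by a-score maximization; memberships are the discriminant
class posteriors. This BIC is calibrated for genotype-PCA score geometry
(noise spread over many comparable axes with n much smaller than the locus
count); on low-dimensional isotropic toys it over-splits, which is why the
tests exercise it on genotype-like data. Migrants are birds whose
membership to a non-natal cluster reaches 50% (ties flagged).
Differentiation is the Weir & Cockerham (1984) multi-locus ratio-of-sums
theta with missing-aware per-locus sample sizes; significance comes from
bootstrapping loci (p = fraction of bootstrap theta <= 0).

## Relatedness

Each pair's nine condensed Jacquard coefficients are estimated by EM on the
standard 9-state genotype-pair emission table (a function of per-locus
allele frequencies), with a fixed miscall rate (default 0.005) mixed into
the emissions because calls are hard genotypes. Kinship is
`phi = D1 + (D3+D5+D7)/2 + D8/4`; classes use the usual kinship
half-interval bands, with parent-offspring vs full-sib split by `D8 > 0.8`.
Allele frequencies are pooled across colonies (the estimator's standard
assumption; mild upward bias for cross-colony pairs). Pruning keeps, per
connected component of first-degree edges, the bird with least missing data.

## Multi-epoch Ne (stairway estimator)

History is parameterized by one scaled population mutation rate
`theta*_k = 4 N_k mu L` per coalescent level (the period with exactly k
ancestral lineages), so the expected unfolded spectrum is linear in the
parameters:

    E[xi_i] = sum_k theta*_k / (k-1) * C(n-i-1, k-2) / C(n-1, k-1)

(the combinatorial factor is an exchangeable-topology identity and holds for
any time-varying Ne). Folded classes are modeled as independent Poisson
counts — the multinomial composite likelihood plus an anchor on the total
SNP count. The Poisson-linear objective is concave, maximized by monotone
multiplicative (Richardson-Lucy) updates. Levels are grouped into `b+1`
blocks sharing a theta; breakpoints are placed greedily (each insertion
maximizes the likelihood — equal-size blocks cannot express the dominant
transition at the 2-3-lineage boundary), and `b` is chosen among
`{1, 2, (n-2)/2, n-2}` by validation likelihood on a random 2/3-1/3 site
split. Times follow from `E[T_k] = 4 N_k / (k(k-1))`; `E[T_k]` under an
arbitrary piecewise-constant history is also available exactly (constant
case) or by a vectorized pure-death simulation, and the two agree within
Monte-Carlo error. Bootstrap bands are pointwise percentiles over
multinomial site resamples on a log-time grid; the decline onset is the
most ancient grid time at which the median trajectory is below half its
ancestral plateau.

Scaling: the counts pin `theta*_k`; converting to Ne divides by
`4 mu L`, so at fixed counts doubling the assumed assay length L halves
both the per-site theta and the Ne estimates.

## Demographic models M1-M7

Seven nested two-colony histories: M1 split+resize only; M2 split followed
by per-colony declines, no gene flow; M3 = M2 with gene flow `2Nm1 = 0.5`
dropping to `2Nm0 = 0.01` at the declines, forward direction RDC -> RIR
only; M4 decline in RIR only with the same gene-flow change; M5 one
pre-split decline; M6 two pre-split declines; M7 pre-split decline plus
post-split per-colony declines with the M3 gene-flow scheme. The migration
values and the 4-generation recent decline time are fixed constants (not
counted in k). Search ranges are log-uniform: sizes 10-1e7 diploids, times
1-2e4 generations, except present-day colony sizes 10-1e3 (census
knowledge; without this bound the likelihood has a degenerate mode that
parks the large ancestral population in a present-day colony, since four
generations of drift leave almost no signature).

Fitting maximizes `sum m_i log10 max(p_i, 1e-8)` over the folded joint SFS
(masked corners excluded), with expected spectra from 20,000 Monte-Carlo
genealogies per evaluation. Because conditioned-SFS *proportions* are
invariant to a joint rescaling of all sizes and times, a Poisson term for
the observed SNP count with mean `mu * L * E[total length]` anchors the
absolute scale (equivalent to supplying the monomorphic class); the assay
length L is carried by the truth log (`L = n_snps / (mu * E[total length])`
at the generating history — the calibration a real assay gets from its tag
count and length). The optimizer runs independent random restarts; each of
40 cycles draws fresh common random numbers, re-scores the incumbent and
marches each free parameter geometrically while the likelihood improves
(step sizes shrink from 0.4 to 0.02 decades). In-search scores are noisy
(the Monte-Carlo error exceeds the contrasts along near-flat directions),
so all endpoints are re-scored at 10x simulation effort under common random
numbers and the leaders get a short 5x-effort polish before the winner is
returned. AIC = 2k - 2 ln(10) max-log10-CL; delta-Lhood is reported
against the saturated (observed-proportions) likelihood. Block-bootstrap
CIs resample 100 contiguous SNP blocks with replacement, refit each
replicate, and use the normal approximation mean +/- t SE.

### What is and is not identified

The folded conditioned 2d-SFS pins dimensionless drift compounds (epoch
duration over 2N), migration-per-drift (the 2Nm constants), and — through
the count anchor — one absolute scale dominated by the deep epoch. The
split time therefore rides an almost exactly flat likelihood ridge (scale
the post-split interval and the post-split sizes jointly), and the
pre-bottleneck ancestral size trades off against the number of lineages
surviving to the deep epoch within a factor of a few. At the study scale
(20,000 SNPs, 10 diploids per colony) alternatives several-fold apart in
these parameters sit within a few log10 units of each other — at or below
evaluation noise. Recovery experiments for those quantities consequently
scatter around the truth by up to several-fold depending on the seed;
recovery of the identifiable compounds is tight and is what the unit tests
assert. Published point estimates for such designs necessarily lean on the
informativeness of their search ranges.

## Problem sizes used by tests and scripts

The end-to-end recovery checks run at the study's stated design: the model
refit uses 20,000 SNPs, 10+10 diploids, 20 restarts, 40 cycles and 20,000
genealogies per evaluation; the decline-onset check uses 33 haploids,
15,000 SNPs and 19 bootstrap trajectories; cluster-count selection uses the
full 87-bird design at 10,000 SNPs. Unit and property tests use smaller
panels (hundreds to a few thousand SNPs, n <= 40 haploids) with tolerances
set by closed forms, enumeration oracles, or 3 standard errors of the
Monte-Carlo estimate; model comparison recovery runs a nested pair (M1 vs
M2) over 10 seeds at 2,000 SNPs. An independently developed coalescent
simulator (msprime) serves as an external oracle for expected TMRCA,
spectra and the island-model F_ST, never as the implementation.

## Known limitations

* Composite likelihoods ignore linkage; CIs are accordingly optimistic.
* The generator emulates genotype calls, not reads: no depth-dependent
  genotype likelihoods, reference bias, or allele dropout.
* The stairway estimator's recent levels carry almost no signal in
  bottlenecked histories and are regularized only by level grouping;
  trajectories are trustworthy where coalescences actually accumulate.
* The two-deme kernel is specialized (at most two demes alive at once),
  which covers the model set but not general island models with 3+ demes.
* Relatedness assumes pooled allele frequencies and outbred reference
  classes; inbred-class Deltas are estimated but classification uses the
  outbred patterns.
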