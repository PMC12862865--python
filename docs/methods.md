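# Methods

This note documents the models, estimators, numerical choices and design
decisions behind `haplopop`, and what the synthetic-data tests do and do
not establish about real data.

## Pseudo-haploid genotypes

All analyses operate on a matrix of single sampled alleles: at each SNP
each individual contributes 0, 1 or missing. This is the standard
genotyping mode for data too shallow for diploid calls: it trades per-site
information for unbiasedness (the sampled allele is a fair draw from the
individual's two copies). Consequences threaded through the package:

- a "genotype" carries binomial sampling noise on top of population
  structure; estimators must average over many SNPs;
- heterozygosity is not observable per individual, so any correction that
  needs it (e.g. the usual finite-sample f3 correction) is unavailable;
- two independent draws from one genome (duplicate libraries, twins)
  mismatch at exactly half the unrelated rate under Hardy–Weinberg
  proportions — the basis of the duplicate screen.

## Synthetic-data generator

The generator emulates the statistical structure of sparse
reduced-representation SNP data from several weakly differentiated
populations. Per SNP an ancestral frequency is drawn Uniform(0.05, 0.95);
population *k* draws its frequency from the Balding–Nichols Beta
distribution `Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)` with mean *p* and
variance `F_k p(1−p)`. Balding–Nichols was chosen because its *F*
parameter equals the Weir–Cockerham θ estimand, giving closed-form truth
for parameter-recovery tests. Diploid genotypes are Binomial(2, q) with
`q = Σ_k a_k p_k` for ancestry proportions *a* (one-hot by default);
pseudo-haploid calls sample one allele; missingness is MCAR with a
per-individual rate (the real mechanism is locus-coverage driven, but the
downstream filters condition only on marginal missing fractions, so MCAR
is sufficient for testing them).

Defaults are calibrated to the weak-structure regime the package targets:
six populations with `F = (0.09, 0.05, 0.03, 0.03, 0.035, 0.09)` (pairwise
θ ≈ (F_i+F_j)/2 ≈ 0.03–0.09), sample sizes (8, 7, 26, 25, 22, 26),
per-individual missing rates Uniform(0.2, 0.6), ten 15 Mb chromosomes.
Planted features: technical duplicates (independent re-haploidization of
an existing diploid genome, appended with `_dup` ids) and migrants
(individuals whose genotypes are drawn from a source population different
from their capture label; pure-source by default, with a
`migrant_source_fraction` option for admixed migrants).

What the generator does **not** model: linkage disequilibrium (SNPs are
independent given population frequencies), coverage-correlated
missingness, genotyping error, null alleles/allele dropout at restriction
sites, or an explicit demographic history (no divergence times or
migration rates — only the marginal drift magnitude). Passing tests
therefore demonstrate correctness of the estimators under their
statistical assumptions, not robustness to these real-data artefacts.
Block-jackknife calibration on this generator is conservative for real
data, where linkage makes nearby SNPs dependent.

## Filters

Site filter 1: minor-allele frequency ≥ 0.01 (computed from pooled
non-missing calls, PLINK `--maf` semantics) and per-SNP missing fraction
≤ 0.5. Site filter 2 (pre-PCA): per-SNP missing fraction ≤ 0.6 and
minor-allele **count** ≥ 3. Individual filter: missing fraction ≤ 0.7.
Missing-fraction denominators are the current, post-upstream-filter
dimensions; MAF is computed after any individual removals, not before.
Pipeline order: site filter → PMR dedupe → individual filter → count
filter. All filters are idempotent and preserve order.

## Duplicate screen

All-pairs PMR is computed by matrix products over observed-call indicator
matrices. Pairs with PMR ≤ 0.6 × the median within-group PMR are flagged
(0.6 sits midway between the duplicate expectation 0.5 and the unrelated
1.0); pairs with fewer than 500 overlapping SNPs are never flagged (at
PMR ≈ 0.2–0.35 an overlap of 500 gives a binomial s.e. of ~0.02, well
below the 0.1+ gap the threshold must resolve). Groups with fewer than
three members fall back to the global median with a logged warning.
Flagged pairs form a graph; per connected component the individual with
the most non-missing calls is kept (ties: lexicographically smallest id,
logged). Components generalize the per-pair rule safely when A–B and B–C
are both flagged.

## PCA with missing data

Per-SNP centring on the observed mean; similarity(i, k) = mean product of
centred genotypes over jointly observed SNPs. Cells are never imputed;
the matrix may be slightly indefinite, so negative eigenvalues are
reported as-is and excluded from the variance-explained denominator.
Cells backed by fewer than `min_pairs` (default 100) joint SNPs are
flagged, not excluded. Eigenvector signs are fixed by making the
largest-magnitude loading positive. Coordinates are raw eigenvector
entries by default; a sqrt-eigenvalue scaling is available (with it, and
all components retained, pairwise distances reproduce the similarity
Gram matrix — the property behind the subset-PCA tests).
`subset_pca` decomposes a row/column submatrix of the *existing*
similarity matrix (no re-centring), which is the operation needed when
dropping duplicates or outlier groups after the matrix is built;
recomputing from genotypes is available separately via `pca` on a subset
dataset and will generally differ.

With zero missingness the method reduces exactly to PCA of the centred
genotype matrix.

## Weir–Cockerham F_ST, haploid form

Calls are single alleles, so the ANOVA has two levels (among groups,
among alleles within groups) rather than the diploid three; the diploid
form is deliberately absent because it would require heterozygosity that
pseudo-haploid data cannot supply. Per usable SNP (≥ 2 groups with data,
positive within-group degrees of freedom, pooled frequency polymorphic)
the locus components `a = MSP − MSG` and `b = MSP + (n_c − 1)MSG` are
accumulated and θ is the ratio of sums (ratio of averages — standard
practice, stable when rare SNPs contribute tiny denominators). Under
Balding–Nichols truth the estimator recovers *F* with |bias| well inside
3 Monte-Carlo standard errors at 2×10⁴ SNPs (tested for F = 0, 0.05,
0.10).

Permutation test: labels are reassigned by a true permutation (sizes
preserved) among the individuals of the listed groups; the identical
statistic is recomputed; `p = (#{θ_perm ≥ θ_obs} + 1)/(n_perm + 1)` with
ties counting as exceedances, computed in exact rational arithmetic. For
pairwise rows the default pool is **all** listed groups (the two-group
variant is available via `scope="pair"`). Permutations on which the
statistic is undefined are redrawn and logged. Type-I error at nominal
0.05 measures 0.04 over 200 null replicates.

## f3 / f4 with block jackknife

Group frequencies are pooled haploid calls; a group contributes wherever
it has ≥ 1 call (no minimum — single-individual outlier groups are a
legitimate use case, at the cost of large per-SNP noise that the
jackknife absorbs into the s.e.). Per-SNP products are averaged
unnormalized (these are f-statistics, not D-statistics).

**No finite-sample bias correction is applied to f3.** The usual
correction subtracts a heterozygosity-based term that is invalid for
single-sampled-allele data; f3 values are therefore inflated by an
additive sampling-noise term that is constant across configurations
sharing the target group, so *comparisons* of f3 values (the supported
use) are unaffected while absolute values should not be interpreted as
drift lengths.

Blocks are greedy contiguous runs per chromosome covering
`[start, start + block_bp)` (default 3 Mb), restarting at chromosome
boundaries. The jackknife is the weighted delete-one form for unequal
block sizes (weights = usable SNP counts): with `h_j = n/m_j`,
`θ_J = g θ̂ − Σ(1 − m_j/n)θ_{−j}` and
`var = (1/g) Σ (h_j θ̂ − (h_j − 1)θ_{−j} − θ_J)²/(h_j − 1)`.
It reduces exactly to the classical delete-one formula for equal weights;
s.e.m. scales as n_SNPs^(−1/2) on homogeneous data (measured slope −0.50).
Fewer than two non-empty blocks → s.e. undefined, flagged. Under a star
topology (no gene flow) the |Z| ≥ 2 rate across all quartets measures
0.04, matching the nominal ~5% and supporting the usual |Z| ≥ 2 reading.

Enumeration is deterministic: f3 over all (target; a < b), f4 over
canonical quartets (a < b, c < d, (a,b) < (c,d)); configurations with no
usable SNPs are kept and flagged unavailable rather than dropped.

## Migrant screen

Candidates are individuals whose nearest group centroid over the top
(n_groups − 1) PCs (own group's centroid computed leave-one-out) differs
from their capture label. Each candidate is then made a singleton group
and tested with `f4(X, candidate; P, Q)` where P is the capture group, Q
the nearest group and X the largest remaining group: if the candidate
truly stems from Q the statistic equals Q's shared-drift variance (> 0),
if from P it is negative, so `Z ≥ 2` confirms the reassignment. Other
candidates are set aside during each test so one migrant cannot
contaminate another's reference groups.

## Reproducibility and problem sizes

Every stochastic operation takes a seed or inherits one from the
pipeline's root seed through named substreams, and all generator outputs
are bit-identical under a fixed seed. The validation suite runs at sizes
chosen to make each check statistically decisive while staying desk-scale:
oracle comparisons on ≤ 10×50 matrices at 1e-10; recovery and duplicate
tests at 2×10⁴ SNPs; permutation calibration with 200 replicates × 199
permutations; f4 calibration with 20 replicates of five populations;
the end-to-end replica (six groups, four duplicate pairs, nine migrants)
at 5×10⁴ SNPs over five seeds, requiring all duplicates and ≥ 7/9
migrants in ≥ 80% of seeds.

One test-design note: a pure-source migrant is statistically exchangeable
with source-population members, so "falls inside the source group's
convex hull on (PC1, PC2)" fails with probability ≈ E[#hull vertices]/n
even for a perfect method; the hull test therefore uses a 150-individual
source population so that it measures placement rather than hull-coverage
combinatorics.

## Known limitations

- No LD modelling anywhere: jackknife calibration on synthetic data is
  optimistic about block-to-block independence compared to real genomes.
- The PCA similarity matrix can be indefinite under extreme or structured
  missingness; eigenvalue signs are reported but coordinates involving
  near-zero eigenvalues are noisy.
- f3 absolute values are biased upward (no finite-sample correction; see
  above).
- The migrant screen assumes the source population is present in the
  sample; a migrant from an unsampled population is flagged at best as a
  nearest sampled relative.
- VCF input assumes diploid GT fields; half-calls become missing rather
  than being used as haploid evidence.
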