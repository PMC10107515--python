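# Methods

`crossploidy` asks a single scientific question of a two-species contact
zone: do a diploid and a tetraploid plant species exchange genes?  It
implements the full inference chain a population geneticist would run on a
reduced-representation (GBS) SNP matrix and a diagnostic marker alignment:
variant filtering, differentiation statistics, hybrid-class assignment, and
joint site-frequency-spectrum (SFS) demographic inference — together with a
synthetic-data generator that produces datasets with the same statistical
structure and a known truth, so every stage can be validated end to end.

## The demographic model

All inference is phrased in terms of an isolation-with-migration history:
one ancestral population of effective size N_e = 1 splits into a diploid
population D and a tetraploid population T.  Four nested families differ
only in when migration is allowed:

| family | free parameters (k) | migration |
|---|---|---|
| `constant_gene_flow`   | ν_D, ν_T, T0, M_DT, M_TD (5) | throughout |
| `historical_gene_flow` | ν_D, ν_T, T0, T1, M_DT, M_TD (6) | only in the older epoch T0 |
| `secondary_contact`    | ν_D, ν_T, T0, T1, M_DT, M_TD (6) | only in the recent epoch T1 |
| `no_gene_flow`         | ν_D, ν_T, T0 (3) | never |

Units: ν are present-day sizes relative to the ancestral N_e; times are in
coalescent units of 2·N_e generations; M is the number of migrant lineages
per generation (M = 2·N_e·m), entering the backward-time structured
coalescent as the per-lineage jump rate.  Because no mutation-rate estimate
is assumed, the ancestral N_e is fixed at 1 and the mutation scale θ is
profiled out analytically, so sizes and times are relative quantities.

Inbreeding coefficients F_D and F_T act at the genotype-sampling stage: at
population allele frequency p a diploid genotype is drawn with
P(het) = 2p(1−p)(1−F), the homozygote classes receiving the complementary
mass.  They are *fixed* (defaults 0.81 for the diploid, 0.75 for the
tetraploid, the values appropriate for highly selfing eyebright
populations), never optimized — high inbreeding and GBS heterozygote
undercalling are confounded, and fitting F jointly with the demography is
not identifiable at a few hundred SNPs.  The tetraploid population is
represented by diploid genotype calls throughout: analyses are restricted
to the subgenome conserved between ploidy levels, where inheritance is
disomic and GBS callers emit diploid genotypes.

## One engine for simulation and inference

The package deliberately uses a single Monte-Carlo engine for both the
data generator and the expected SFS, so that parameter-recovery tests probe
estimation error, not model mismatch.

The engine simulates two-deme structured-coalescent genealogies of a finite
*pool* of lineages (default 100 per population) and accumulates, over
genealogies, the total branch length subtending each pool configuration
(i copies in D, j copies in T).  Under the infinite-sites model the
expected number of segregating sites with configuration (i, j) is
proportional to this weight.  The accumulation is Rao-Blackwellized (every
branch contributes, not a single sampled mutation) and O(#events) per
genealogy, since a lineage's subtended configuration is constant over its
lifetime.  A batch-means estimator supplies a per-cell Monte-Carlo standard
error, which the spectrum carries along through folding and projection.

* **Simulation** draws each site's pool configuration i.i.d. from the
  normalized weights — the length-biased mixture over genealogies, which is
  the correct generative counterpart of the expectation (weighting all
  genealogies equally would under-represent long genealogies) — then treats
  i/pool as the population frequency and samples individual genotypes with
  the inbreeding-distorted probabilities above.  Only matrix-segregating
  sites are retained, each assigned its own scaffold (an unlinked GBS-like
  SNP panel).
* **Expectation** maps the same weights through (i) the exact distribution
  of the inbred genotype sum of the sampled individuals (an n-fold
  convolution per pool frequency) and (ii) the hypergeometric projection to
  the target haploid sample size.  Both maps are precomputed matrices, so
  one likelihood evaluation is a kernel run plus two small matrix products.

The finite pool introduces an O(1/pool) upward bias in F_ST-type
statistics (sampling genotypes from a finite frequency grid adds a little
between-population variance).  At the default pool of 100 this is below
~0.01 on F_ST; the oracle tests that compare the engine against an
independent coalescent simulator (msprime) run at pool 400, where the bias
is inside the Monte-Carlo envelope.  The pool size is a precision knob, not
a model parameter.

## Joint SFS, missing data, folding

The observed joint SFS counts minor-allele configurations over the two
populations.  Missing genotype calls are absorbed in the standard way: each
site's allele count over its non-missing calls is redistributed with the
product of two hypergeometric kernels onto a fixed target size (24 haploid
genomes per species by default); sites with fewer called haploids than the
target are dropped.  Spectra are folded by default — the SNP panel has no
outgroup polarization — and the fixed corners (0,0) and (n_D, n_T) are
always masked.  Folding and projection commute exactly (tested to 1e-12
against exhaustive enumeration of subsamples).

## Composite likelihood, fitting, model comparison

Treating unmasked cells as independent Poisson counts, the mutation scale
has the analytic maximizer θ̂ = Σdata/Σmodel, and the composite
log-likelihood follows directly.  Fitting is a bounded derivative-free
search in log10-parameter space (bounds 1e-3..100 for sizes and times,
1e-4..50 for M) from randomly perturbed start points (each parameter of the
default start multiplied by 2^U(−1,1)).  Two numerical choices matter:

* **Common random numbers**: within a search stage every likelihood
  evaluation reuses one Monte-Carlo seed, making the objective a
  deterministic function of the parameters.
* **Pattern search, two stages**: the surface is still rough between
  distant points, and simplex-style local search stalls on it.  The
  optimizer is a greedy coordinate pattern search with halving steps —
  moves are only accepted between points at least a step apart, keeping
  real likelihood differences above the noise — run first coarsely
  (default 1000 genealogies per evaluation) from every restart, then
  polished from the best restart at 8x precision.  The reported
  log-likelihood is a final evaluation at the refined precision with an
  independent seed, so restart selection noise does not leak into AIC.

Uncertainty is assessed exactly as in the subsampling protocol: the
projected SFS is rebuilt from without-replacement subsets of individuals
(replicates), every model family is fitted to every replicate, and families
are compared by median AIC (AIC = 2k − 2lnL, exact by construction) with
Welch two-sample t-tests of each family's AIC distribution against the
best family's.  The composite likelihood is valid for ranking, not as a
literal probability; the t-test is the same descriptive device the
subsampling protocol implies, not a calibrated test.

Default restart counts in the orchestrated pipeline (3 restarts, 3
replicates) are deliberately small — the full 99 x 99 protocol is available
by passing `n_restarts=99`, `n_replicates=99`, and problem sizes in the
test-suite harnesses (10,000 sites for recovery checks, 20 seeds) were
chosen so a complete validation run finishes on a single CPU in minutes.

## Differentiation statistics

* **Per-SNP F_ST** is the Weir & Cockerham (1984) two-population θ from
  diploid calls (components a, b, c, including the heterozygosity terms);
  negative estimates are retained, undefined sites (a+b+c = 0, or a
  population without calls) are flagged.  The *global* value is the
  unweighted mean of defined per-site estimates; the ratio-of-sums
  alternative (Σa/Σ(a+b+c)) is also reported, and with a rare-variant-heavy
  spectrum the two can differ substantially — the histogram (bin width
  0.05) makes the bimodality visible.
* **AMOVA** is the one-level Excoffier sums-of-squares partition on squared
  pairwise distances (squared Euclidean on mean-imputed allele-count
  vectors for SNPs; Hamming proportion on comparable columns for
  alignments), with Φ tested by label permutation and the +1-corrected
  p-value, 9999 permutations by default.
* **PCA** mean-imputes missing dosages per site, centers (optionally
  scales — the default is unscaled, matching common practice for dosage
  matrices), and reports SVD scores and per-axis variance percentages.

## Hybrid detection

Two independent analyses, deliberately kept separate so their agreement is
informative:

* **Admixture proportions** (`AdmixtureEM`): the K = 2 binomial admixture
  model g_il ~ Bin(2, q_i p_1l + (1−q_i) p_2l), fitted by EM; 90% intervals
  by parametric bootstrap (genotypes resampled from the fitted model, 200
  replicates, percentile interval, interval forced to bracket the point
  estimate); label switching resolved by anchoring cluster 1 to the labeled
  diploid samples.  The *nonhybrid rule* declares an individual nonhybrid
  when its interval overlaps 0 or 1 (numerical guard 1e-6).
* **Six-category classification** (`HybridClassifier`): categories
  {PureD, PureT, F1, F2, BC_D, BC_T} are defined by their Mendelian
  proportions of per-locus ancestry pairs (D,D)/(D,T)/(T,T); the per-locus
  genotype likelihood mixes pair-conditional cross probabilities at the
  parental allele frequencies, which are refined by EM with the category
  posteriors (uniform category prior).  A subtlety worth knowing: with
  perfectly diagnostic loci, F2 and backcross both predict heterozygosity
  1/2 per locus, so those two categories can only be separated by
  homozygote patterns — power for F2-vs-BC is intrinsically lower than for
  F1-vs-anything.

The synthetic positive controls (`inject_hybrids`) draw hybrid genotypes by
per-locus Mendelian gamete sampling from randomly chosen parents, so the
classifier is tested against its own generative assumptions plus the
realized parental frequencies.

## What the generator does and does not emulate

The defaults describe a realistic mixed-ploidy contact zone: 45 diploid + 50
tetraploid individuals, 356 unlinked biallelic SNPs, strong inbreeding
(F = 0.81/0.75), a constant-gene-flow history with M = (0.3, 0.4) migrants
per generation and a split one coalescent time unit ago, optional GBS-like
missingness (default rate 0.1 where enabled — a placeholder, since the true
missingness profile of a GBS matrix depends on library preparation), and an
ITS-like 658-bp alignment with 58 fixed inter-group differences plus rare
singletons.  Real GBS data additionally feature allele-specific dropout
(heterozygote undercalling), depth-dependent missingness, paralog
collapse, and SNP-ascertainment against rare variants; none of these are
modeled.  Passing tests therefore demonstrate correctness of the
*inference machinery* under the stated model, not robustness to every GBS
artifact — in particular the synthetic per-SNP F_ST distribution carries
more low-frequency, low-F_ST variants than an ascertained GBS panel, which
depresses the mean-of-sites global F_ST relative to the ratio-of-sums
estimator.

## Degenerate inputs and numerical guards

Model cells that are zero where data are positive are floored at 1e-12 and
logged; an empty data spectrum yields (lnL, θ̂) = (0, 0) and a warning;
allele frequencies in the EM algorithms are clipped to [1e-6, 1−1e-6]; EM
non-convergence is flagged on the result, never silent; a fully missing
individual keeps its row (uniform posterior, flagged) rather than being
dropped.  Filter thresholds are strict inequalities (a site missing in
exactly half the individuals survives a 50% filter), matching the usual
reading of ">50%" rules, and per-scaffold pruning keeps the lowest-position
variant deterministically.

## Known limitations

* Relative parameters only: no mutation-rate calibration, hence no absolute
  N_e or times in generations.
* Composite-likelihood AICs understate uncertainty when sites are linked;
  the one-variant-per-scaffold filter is what justifies the independence
  assumption here.
* The Monte-Carlo expected SFS makes likelihood surfaces locally rough;
  the pattern-search optimizer is robust to this but parameter ridges
  (ν against T0 trade-offs) remain, exactly as with deterministic
  diffusion-based spectra at these data sizes.
* K is fixed at 2 in the admixture model; tetrasomic genotypes, linkage
  within scaffolds, and selection are out of scope.
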