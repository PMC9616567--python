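# Methods

## Site frequency spectra from genotype posteriors

Genotype uncertainty enters as per-site, per-individual posterior
probabilities of the diploid genotypes 0/1/2. The allelic dosage
E[G] = Σ_g g·P(G=g) is summed over a population's individuals and rounded
half-up to an allele count; sites with any missing individual are dropped
so the sample size n is fixed. Monomorphic sites contribute to the
callable totals L_S/L_N only; derived-fixed sites (unfolded spectra with
an ancestral call) increment the fixed differences dS/dN. Rounding is
exact in the one-hot limit and transparent otherwise; maximum-likelihood
SFS estimation from genotype likelihoods is deliberately out of scope.

Bootstrap replicates of a spectrum are multinomial draws with trials equal
to the callable total and category probabilities equal to the observed
proportions of (frequency bins, fixed differences, invariant remainder),
independently for the synonymous and nonsynonymous classes. Including the
fixed differences in the multinomial (rather than holding them fixed)
propagates divergence-count noise into downstream α confidence intervals,
which are computed by refitting on these replicates. Every replicate
preserves the callable total exactly.

## Equilibrium PRF with a gamma DFE

The selection model is the equilibrium Poisson random field. A deleterious
mutation with scaled coefficient S = 2N_e s ≥ 0 has stationary sojourn
density

    tau(q; S) = (e^(−2Sq) − e^(−2S)) / ((1 − e^(−2S)) · q(1 − q)),

which is 1/q at S = 0, so the neutral limit of the expected spectrum is the
Watterson expectation θL/i. The expected unfolded bin counts are

    E[ξ_i] = θ_N L ∫ gamma(S; k, m) ∫ tau(q; S) C(n,i) q^i (1−q)^(n−i) dq dS

with the DFE a gamma distribution over S with shape k and mean m. The
frequency integral uses 400-node Gauss–Legendre quadrature with the
bounded form of tau (safe at large S); the gamma mixture uses 200
log-spaced cells from 10⁻⁸ to S_max = 5000 with exact cell masses from the
gamma CDF, the mass below the grid treated as neutral and the mass above
evaluated at S_max. Against nested adaptive quadrature the combined scheme
is accurate to ~10⁻⁴ relative for smooth gamma DFEs; it is not intended
for point-mass DFEs (the log grid then resolves the atom only to the cell
width).

Fitting maximizes the Poisson likelihood of the (optionally folded)
nonsynonymous bins over (log k, log m) by Nelder–Mead from five starting
points. θ_S comes from Watterson's estimator on the synonymous spectrum
and θ_N = 2.76·θ_S is held fixed — the 0-fold/4-fold mutation-rate ratio —
so that variants removed by strong selection are accounted for instead of
deflating θ. The fitted DFE is discretized at 2N_e s = 1 and 10 into
nearly neutral / intermediate / deleterious mass. Between-set bin
comparisons use doubled-overlap bootstrap p-values,
p = 2·min(Pr*(Δ≤0), Pr*(Δ≥0)) over paired replicate differences, clamped
so the smallest attainable value is 2/reps. The paired-difference (not
marginal-overlap) reading of the doubled overlap is the implemented
convention.

No demographic model is fitted: the generator and the inference share the
equilibrium assumption so that recovery is well-posed, and
`expected_sfs_gamma` accepts per-bin distortion multipliers through which
a separately fitted demography could be plugged in. Demographic
misspecification testing is a non-goal.

## Asymptotic rate of adaptive evolution

α(x) = 1 − (pN(x)/pS(x))/(dN/dS) per unfolded frequency bin (bins with
pS(x) = 0 masked), extrapolated with α(x) = a + b·e^(−cx). A brute-force
scan of the (a, b, c) box [−1,1]×[−2,2]×[0.1,50] at 20 points per axis
seeds a bounded trust-region least-squares refinement; the reported α is
the fitted curve at x = 1 (stated alongside a, which is the x→∞ value).
By default the fit can exclude low-frequency bins (`x_min`): the
singleton/low-count classes are dominated by weakly deleterious variants
(and in real data by sequencing error), and on the model's own noise-free
α(x) curve at n = 20 (shape 0.3, mean 400) their inclusion biases the
extrapolated asymptote from 0.28 down to 0.23 against a truth of 0.30.
The recovery experiments use x_min = 0.175 (the three lowest count classes
at n = 20). Percentile 95% CIs come from refitting on multinomial
bootstrap spectra (300 replicates in the shipped experiments), warm-
started from the point estimate.

Gene-set versus genome comparisons use a Gaussian-error LRT on the pooled
fit: statistic N·ln(RSS₀/RSS₁) with 3 degrees of freedom, the form implied
by likelihood-ratio testing of nested nonlinear least-squares fits.

## Diversity, differentiation, Tajima's D

π sums the unbiased per-site heterozygosity 2c(n−c)/(n(n−1)) over variant
sites and divides by all callable sites. F_ST uses the Weir–Cockerham
(1984) variance components a, b, c computed per site from rounded-dosage
genotypes (heterozygosity from the genotype calls) and summed over sites
before the ratio Σa/Σ(a+b+c) — ratio of sums, not mean of per-site ratios;
negative estimates are reported as-is (truncation available as a flag).
Tajima's D uses the standard a₁…e₂ constants; the pairwise-difference
weight i(n−i) is symmetric under folding, so folded spectra are handled
identically. TE presence/absence loci are treated as biallelic sites from
the discretized genotypes.

Gene-set CIs resample genes with replacement (default 1000 draws) and
recompute the statistic from the resampled genes' summed components, so a
resample containing every gene exactly once reproduces the point estimate.
Percentile intervals are reported (the CI flavour is labelled; BCa is not
implemented).

## Differential expression and methylation

Expression tests follow the ladder `~ population + field` vs
`~ population` (field), `~ field + population` vs `~ field` (population),
and the interaction row, per gene, on negative-binomial GLMs with log link
and median-of-ratios size factors as offsets. The per-gene dispersion is
estimated under the full model by Cox–Reid adjusted profile likelihood
(−½·logdet(XᵀWX) penalty); without the adjustment the dispersion MLE is
biased low and the tests anticonservative. Because the dispersion is
estimated rather than known, the LRT statistic is referred to
F(df, residual df) rather than χ²_df; at the shipped study design (36
samples, dispersion 0.1) this calibrates the null type-I error to ~0.05
where the χ² reference gives ~0.08. Genes that fail to converge keep
p = 1 with a flag and stay in the multiplicity denominator. Field and
population tests are flagged at Bonferroni p < 0.05, interaction tests at
Q < 0.05 (the sample-size-preserving convention for the rare interaction
outliers). Dispersion shrinkage, Cook's filtering and variance-stabilizing
transforms are non-goals.

Methylation treats the diploid methylome as two alleles: per gene and
individual, the methylated allelic dosage is 2·Σ per-cytosine methylation
proportions (unmethylated its complement), after removing sites with ≤ 3
reads and cytosines missing in ≥ 50% of individuals; meth + unmeth =
2·n_cytosines holds exactly. Genes need ≥ 10 cytosines. The dosages are
compared across the same ladder with binomial-weighted logistic
regressions (weights = total dosage; fractional totals are handled as
weighted likelihood on proportions, i.e. quasi-likelihood), with the
per-sample genome-wide non-CG methylation rate (CH%) as a covariate for CG
tests — the per-sample (not per-gene) reading of the covariate is the
implemented choice. Flagging is at Q < 0.05; Q-values are
Benjamini–Hochberg by default with a Storey-style π₀ option (unstable at
small m, hence not default). LRT statistics can be genomic-control
corrected: λ = median(stat)/median(χ²_df), statistics divided by λ only
when λ > 1.

The CG-context dosage model is exactly specified under the generator (see
below) and its null p-values are uniform; the pooled CH test mixes CHG and
CHH baselines and is therefore mildly conservative (a sum of non-identical
binomials is underdispersed relative to one binomial) — a property shared
with real data, not an artifact.

Promoter-region analyses reuse the dosage machinery on strand-aware 1 kb
upstream intervals truncated at contig edges.

## Methylome and TE operations

Methylation levels are read-weighted means Σmeth/Σtotal per context ("CH"
pools CHG+CHH). Conversion efficiency is 1 − Σmeth/Σtotal on the
chloroplast, which is naturally unmethylated. Meta-feature profiles map
feature bodies to 20 relative bins and ±2 kb flanks to 10 absolute bins,
reversing minus-strand features; bin values are unweighted means of
per-site proportions, and features shorter than one bp per body bin are
skipped with a count.

TE-family expression counts accept a read only if every feature it
overlaps is a TE of one family — reads touching genes or two families are
excluded, multi-mapping within a family is allowed. Read-support
proportions discretize to genotypes with > 0.85 → homozygote, 0.15–0.85 →
heterozygote (boundaries inclusive to the heterozygote), < 0.15 → absent,
and coverage < 6× → missing. Composition shares are dosage-weighted with
insertion-resampling CIs. Distances between features are boundary gaps
(0 when overlapping; chromosomes without partners signal missing rather
than infinity); the gap is the least-assumption anchor since no reference
point is canonical. Depth equalization across populations is represented
as an individual-subsampling utility over the insertion table.

## Enrichment and sweep outliers

Fisher tests are exact and two-sided on the 2×2 candidate-set × feature
table; the odds ratio uses a Haldane 0.5 correction (flagged) when a cell
is zero, and OR CIs resample universe genes (case resampling, 1000 reps).
GO enrichment is upper-tail hypergeometric per biological-process term
with Q-values; the universe is the set of genes with ≥ 1 term, so
unannotated genes are excluded from both margins. Sweep outliers: a
gene's score is the maximum window statistic within ±2 kb of the gene
body, flagged when strictly above the linearly interpolated 99th
percentile of the simulated-null scores. GERP RS scores are rescaled to
(rs − min)/(max − min) per site and clipped to [0, 1].

## Synthetic data

The generators produce every input with known truth under the study
conditions: 3 populations × 2 field sites; 6 individuals per
population×field cell for expression and 4 for methylation; θ = 0.005 per
synonymous site with θ_N/θ_S = 2.76; gamma DFE shape 0.3 and mean
2N_e s = 400; adaptive fixation fraction 0.3; NB dispersion 0.1 with
log-normal baseline expression (median 100) and log2 fold-change 2 for
planted effects in 5% of genes; observed methylation levels 30/10/3.5%
for CG/CHG/CHH (contexts mixed 1:1:2 per gene, 60 cytosines per gene so
the ≥ 10-CG filter is satisfiable) with bisulfite conversion failure
0.009, i.e. 99.1% efficiency; TE insertion frequencies from a
singleton-skewed spectrum with Gaussian read-support noise (sd 0.05) and
Poisson coverage (mean 20).

Two modelling choices matter for calibration. First, methylation is
generated at the epiallele level: each cytosine of an individual carries
a ~ Binomial(2, p) methylated alleles and reads sample a/2 (plus the
conversion-failure floor), so the gene-level allelic dosage is itself
binomial in 2·n_cytosines trials — exactly the differential-methylation
model, making null p-values uniform. Generating methylated reads directly
as Binomial(depth, p) would make the dosage test grossly underdispersed
and its null calibration meaningless. Second, divergence counts carry
nonadaptive fixations at the gamma-DFE fixation-probability reduction
E[2S/(e^(2S)−1)], inflated by 1/(1−α_true), so the asymptotic-α estimand
equals the configured adaptive fraction.

What the generators do not emulate: linkage disequilibrium and
recombination (sites are independent), read-level artifacts (FASTQ
simulation is a non-goal), demographic non-equilibrium, batch effects,
and context-specific conversion failure. Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not robustness to demographic or technical misspecification.

## Problem sizes in the shipped experiments

The test suite and the acceptance script use: DFE recovery at n = 20
haplotypes and 10⁶ sites per class; α recovery at 10⁵ sites per class
with 100 simulation replicates × 300 bootstrap refits; null calibration
of both differential tests at 1000 genes (permuted labels on effect-free
data — permuting labels on data with planted effects leaves residual
overdispersion that the dosage-logistic model, which has no dispersion
parameter, cannot absorb); oracle equivalence over exhaustive 2×2 tables
up to total 18 plus a step-5 lattice to total 40; and a 10,000-draw null
for sweep calibration. These sizes make each stage's sampling error small
relative to the tolerances tested while keeping the whole suite
desk-scale.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive at file boundaries (VCF/GFF) and
converted at the I/O layer only. Dosage rounding is half-up. Tajima's D
with zero segregating sites raises a typed error rather than returning
NaN. Optimizers: Nelder–Mead with five starts for the DFE (failure after
all starts raises), grid + bounded least squares for α. Infinite sweep
scores are rejected as input validation. All generators and bootstrap
routines accept either an integer seed or a numpy Generator and are
bit-reproducible for a given seed.
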