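# Methods

`nsa` implements the statistical core of an ancient-DNA ancestry-decomposition
analysis: pseudohaploid genotype handling, f-statistics with block-jackknife
errors, qpWave/qpAdm-style rank tests and admixture-weight estimation,
supervised maximum-likelihood ancestry proportions, PCA projection of
low-coverage individuals, coverage-based sex determination, mismatch-rate
kinship classification, and a burial-association testing battery. This note
records the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Genotype model

Low-coverage ancient samples are represented as *pseudohaploid* calls: at each
targeted variant one sequencing read is drawn uniformly at random among the
quality-filtered reads and the individual is treated as homozygous for its
allele. Calls are stored as {0, 2} so that allele-frequency code treats all
individuals uniformly; a pseudohaploid call contributes **one** sampled allele
to population frequencies and allele counts, a diploid call two. In
single-strand mode (non-UDG single-stranded libraries), forward-strand reads
are ignored at C/T polymorphisms and reverse-strand reads at G/A polymorphisms
before the draw, removing the strand on which post-mortem deamination can
mimic a true allele. Per-site draws are keyed on
(seed, individual index, variant index) through a counter-based seed
derivation, so calling is reproducible and independent of iteration order.

File I/O uses the EIGENSTRAT-dialect triplet (one ASCII digit per call per
line-per-variant; 9 = missing; genetic positions in Morgans on disk,
centimorgans in memory). The `.ind` file carries no ploidy field; at read time
ploidy is supplied explicitly or auto-detected (a row without any heterozygous
call is taken as pseudohaploid), and the optional era annotation does not
round-trip. Variant coordinates are 1-based inclusive; region masks (e.g. an
HLA-scale exclusion) are half-open 0-based intervals. Filtering order is
fixed: region mask, then individual call-rate (computed on the masked set),
then variant call-rate (computed on the remaining individuals); the default
threshold for both is 95%.

## Synthetic data

The generator draws allele frequencies on a *population tree* under the
Balding–Nichols model: each branch with drift parameter F draws the child
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) around the parent's p, so
E[(p′−p)²] = F·p(1−p). Ancestral frequencies are Uniform(0.05, 0.95); the
desk-scale genome is 22 chromosomes × 10 Mb with a linear map at 1 cM/Mb
(≈ 44 five-cM jackknife blocks).

A star tree (every population drifting independently off the root) makes all
populations exchangeable, and then every f4(X, base; R, base) has the same
expectation regardless of X — admixture weights would be unidentifiable. The
default North-Sea scenario therefore hangs the 11 outgroups off structured
clades: a northern clade carrying the CNE-like source plus
Denmark/Sweden/Poland/Finland/Netherlands-like outgroups, a western clade with
the WBI-like source plus Ireland/Wales-like outgroups, a southern clade with
Italy/Spain/Belgium-like outgroups (and the France-IA-like source in the
three-way model), and a deep YRI-like outgroup. Default branch drifts: 0.05
to the European ancestor, 0.015 per clade, 0.005 per source terminal, 0.02–
0.06 for outgroup terminals, 0.15 for the deep outgroup. These are modelling
choices tuned to the realistic regime of closely related northwestern
European populations (source–source Hudson FST ≈ 0.02); they are what the
recovery results are conditional on.

Admixed individuals draw each allele's source population by the mixing
weights, then the allele Bernoulli(source frequency); missingness masks calls
independently at a configurable rate. Sex-chromosome read counts are Poisson
at the targeted-site × depth scale of a 1240K-style capture (1.15 M
autosomal, 49 k X, 32 k Y sites), with X and Y at half depth in XY
individuals and a 0.1% autosomal-depth mismapping floor on the Y of XX
individuals. Relative pairs copy the underlying diploid genotype across 1-Mb
windows covering genome fractions 1, 1/2, 1/4 and 0 (identical, first,
second degree, unrelated) before independent pseudohaploid sampling. Grave
goods are Bernoulli draws from a logistic model in ancestry fraction, sex and
their interaction.

What the generator does **not** emulate: linkage disequilibrium within blocks
(variants are independent given the tree), ascertainment bias of the capture
panel, reference bias, contamination and damage beyond the strand rule,
age-structured sampling, and realistic cemetery family structure. Passing
recovery tests therefore demonstrate correctness of the estimators under the
stated sampling models, not robustness to those artefacts.

## f-statistics

Population frequencies are allele-count weighted (diploid = 2 alleles,
pseudohaploid = 1). The implemented statistics per variant:

- f2(A,B) = (pA−pB)² − hA/nA − hB/nB,
- f3(T;A,B) = (pT−pA)(pT−pB) − hT/nT,
- f4(A,B;C,D) = (pA−pB)(pC−pD),
- FST: Hudson ratio-of-averages with numerator (pA−pB)² − hA/nA − hB/nB and
  denominator pA(1−pB) + pB(1−pA),

with h = p(1−p)·n/(n−1) the unbiased within-population heterozygosity. The
correction needs n ≥ 2 alleles and is skipped (flagged) for singleton
populations. Treating pseudohaploid calls as single allele draws is the
"inbreed" convention appropriate for random-read data. Each statistic uses
every variant at which all its populations have data ("allsnps" behaviour); a
strict global-intersection mode is not needed for the synthetic panels but
the per-statistic masks are respected everywhere. Under the Balding–Nichols
two-population model the Hudson ratio of averages converges to the per-branch
F itself (E[num] = 2F·p(1−p), E[den] = 2·p(1−p)), which is the value the
tests pin.

Standard errors use a weighted delete-one-block jackknife over 5-cM genetic
blocks (physical position × 1 cM/Mb as fallback), blocks never crossing
chromosomes, with Busing-style weighting by per-block variant counts. For
vector statistics the same pseudovalues give a jackknife covariance that
reduces to the classical (g−1)/g outer-product form at equal block sizes.

## Rank tests and admixture weights

For left populations L and right populations R, the matrix
X[i,j] = f4(L₁, L_{i+1}; R₁, R_{j+1}) has rank equal to the number of
independent ancestry streams relating L to R. The rank-k test fits the best
rank-k approximation under the jackknife-covariance metric (alternating
generalised least squares on the two low-rank factors) and refers the
minimised quadratic form to (l−1−k)(r−1−k) degrees of freedom.

Weights for a k-way mixture target T are the constrained GLS solution of
e_j(w) = f4(T, base; R_j, base) − Σ_a w_a f4(S_a, base; R_j, base) with
Σw = 1, where base is the first outgroup. The residual covariance depends on
w, so the solve is iterated to a fixed point. Weights may leave the simplex;
infeasibility is reported, never clipped. Standard errors come from
delete-one-block refits of the *full* procedure — the f4 covariance and the
residual metric are re-estimated inside each replicate — so they carry the
noise of the estimated GLS metric, which at ~44 blocks is a material
variance component (holding the metric fixed under-covers the true weight
by several points); the fit p-value
refers the residual quadratic form to r − k degrees of freedom (the
left-set rank-(k−1) convention). The default outgroup set has 11 members.

**P-value convention.** The covariance is estimated from g jackknife blocks,
and at desk scale g (≈ 44) is not large relative to the statistic dimension;
a plain chi-square on the quadratic form is then anticonservative. The
default convention maps the statistic through the Hotelling-T²/F
transformation, F = stat·(g−d)/(d·(g−1)) on (d, g−d) degrees of freedom,
falling back to chi-square when g ≤ d+1. The choice is recorded in result
metadata and its calibration — uniform fit and rank p-values under correct
models — is asserted by simulation in the test suite, which is the binding
requirement. Singular covariances are ridge-regularised with
ε = 10⁻¹⁰·trace/dim and the ε used is reported.

## Supervised ancestry proportions

The supervised model fixes K labelled source populations and estimates each
target individual's mixing proportions q on the simplex from the haploid
log-likelihood Σ_j [a_j log Σ_k q_k f_kj + (c_j−a_j) log Σ_k q_k(1−f_kj)],
with a_j alternate alleles among c_j observed (pseudohaploid c = 1, diploid
c = 2).

The source frequencies f are **parameters, not plug-in constants**: reference
individuals are pinned to their label corner and the frequency M-step pools
reference allele counts with the targets' responsibilities, as when the
standard supervised-clustering tool is run once over reference plus ancient
individuals. This matters: plugging empirical panel frequencies into a
fixed-frequency likelihood is an errors-in-variables estimator whose score at
the simplex boundary has positive expectation ≈ V/n_ref_alleles — with
100-sample panels that inflates a zero-ancestry individual to ~15–20%
estimated minority ancestry, while the joint update leaves it sub-percent
(the target's own alleles in the frequency estimate orthogonalise the
residual). The plug-in mode is retained (`update_freqs=False`) for
comparison, and a regression test demonstrates the bias it carries.

Optimisation is expectation–maximisation accelerated by squared secant
extrapolation (SQUAREM) with a likelihood safeguard, so monotonicity holds;
convergence is a per-individual likelihood gain below 10⁻⁶ per cycle or,
in joint mode, all proportions moving less than 10⁻⁶ (the ~10⁵ frequency
parameters keep improving microscopically long after the proportions have
stabilised). The multi-start (each corner pulled just inside the simplex,
plus the barycenter) runs on the fixed-frequency surface — concave in each
individual's q, so the starts act as a safety net — on a deterministic
variant subsample at large V; the joint refinement then runs once from the
winning start. Frequencies are clipped to [10⁻⁵, 1−10⁻⁵]. Identical source
panels make the likelihood flat; the estimator detects this, returns the
barycenter and flags non-identifiability.

Standard errors bootstrap variants (default 1,000 replicates) and **refit the
full estimator per replicate** (joint frequency update included, warm-started
from the point estimate): holding the fitted frequencies fixed would miss the
frequency-chasing variance component and roughly halve the SE. A block
bootstrap over 5-cM blocks is available for data with linkage. Estimates from
fewer than 1,000 non-missing variants are flagged and get no SE.

Population summaries report the mean of individual point estimates with
s.e.m. = σ/√n (sample σ, n−1 denominator; undefined at n = 1). The ancestry
class is CNE iff q_CNE > 0.5 (strict), with an unadmixed flag at
q_CNE > 0.95.

## PCA projection

Reference variants with more than 5% missingness are dropped and residual
missing reference calls mean-imputed; calls are centred by the reference mean
and scaled by √(p(1−p)). Components come from the SVD of the standardised
reference matrix. A target individual is projected by ordinary least squares
over its non-missing variants — the least-squares projection convention for
incomplete ancient samples — so a complete-data reference individual
reproduces its reference coordinates exactly. Projections from fewer than 100
usable variants are flagged (NaN coordinates).

## Sex determination and kinship

Sex: X and Y per-site coverages normalised by autosomal per-site coverage.
Expected rates are (1, 0) for XX and (0.5, 0.5) for XY; the SE is
rate·√(1/n_chr + 1/n_aut) by Poisson propagation. Call thresholds (a
decision, since only the expected rates are canonical): XX if x-rate ≥ 0.8
and y-rate ≤ 0.1; XY if both rates in [0.35, 0.65]; otherwise indeterminate.
The complementary rule on the Y fraction of sex-chromosome reads calls XX
below 3% and XY above 35%. Both rules agree on ≥ 99% of simulated
individuals at ≥ 0.1× depth.

Kinship: the pairwise mismatch rate (PMR/P0) between pseudohaploid vectors in
non-overlapping 1-Mb windows, SE by delete-one-window jackknife, minimum
overlap 3,000 jointly covered variants (below: flagged, unclassified).
Normalising by the cohort baseline — the median pairwise PMR, robust to a
minority of related pairs; with fewer than five pairs it must be supplied —
gives expectations 0.5 / 0.75 / 0.875 / 1.0 for identical / first / second /
unrelated under pseudohaploid sampling, classified at the midpoint cutoffs
0.625 / 0.8125 / 0.90625 (the READ convention, exposed in configuration).
Beyond second degree the pseudohaploid PMR is weakly identifying and no
third-degree call is attempted.

## Association battery

Individuals are classified CNE/WBI at the 50% rule and cross-tabulated
against grave-good flags: any goods (all individuals, females, males),
brooches (females), weapons (males), each overall and per site, plus an A/B
burial-configuration table — all with the two-sided Fisher exact test
(probability-mass summation; sample odds ratio with Haldane 0.5 correction
at zero cells). Each Fisher row has a continuous-ancestry companion
comparing q_CNE between flag-positive and flag-negative individuals with the
Wilcoxon rank-sum test (exact null for tie-free combined n ≤ 20, otherwise
the tie- and continuity-corrected normal approximation). Missing flags and
indeterminate-sex individuals are excluded per-test. P-values are reported
unadjusted, matching how such batteries are conventionally reported; an
optional Benjamini–Hochberg column makes the multiplicity visible. Null
calibration: Fisher's exact p is discrete and conservative by construction,
so the uniformity check in the tests applies the Kolmogorov–Smirnov test to
the near-continuous rank-sum p-values and asserts bounded type-I error for
the Fisher tests.

## Pipeline

`nsa.pipeline.run` executes simulate → QC → f-statistics → admixture →
ancestry → association from a YAML/dict config with one global seed; stage
seeds are SHA-256 hashes of (seed, stage name), so adding stages never
perturbs earlier ones. Each stage writes TSVs plus a manifest entry with
parameter and output hashes; a rerun with the same config is bit-identical,
and a failing stage leaves a manifest recording partial completion.

## Problem sizes used in the checks

Recovery checks run at 100,000 variants with 20-sample source panels
(10-sample extra-drifted panels for the ancient-proxy configuration), 10
samples per outgroup, 20-sample targets and 50 replicate simulations;
zero-ancestry calibration uses 50 pseudohaploid targets at 10% missingness
against 100-sample panels; congruence uses a 100-individual 0–100% gradient
at 20,000 variants; interval-coverage and null-calibration simulations use
10,000–20,000 variants with proportionally smaller panels. These sizes are
the package's validation conditions; the estimators themselves have no
built-in scale assumptions.

## Known limitations

- The desk-scale genome yields ~44 jackknife blocks; the Hotelling-F
  convention keeps tests calibrated, but covariance estimates are noisier
  than with a real genome's ~700 blocks.
- Supervised SEs assume exchangeable variants unless the block bootstrap is
  chosen; with real, linked data the block bootstrap is the safer default.
- The association battery reproduces the descriptive testing procedure; it
  is not a multiple-testing-controlled discovery procedure.
- Second- versus third-degree relatives are not separable from pseudohaploid
  PMR alone.
- Merging drops strand-ambiguous (A/T, C/G) variants by default because a
  strand flip cannot be told from an allele flip without frequency matching.
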