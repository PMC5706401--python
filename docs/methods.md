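# Methods

This note documents the statistical models the package implements, the
assumptions behind them, the synthetic-data generator that exercises them,
and the numerical conventions and design choices a maintainer would want
explained.

## Excess AD mortality on genealogies

Every individual with a known birth year is assigned to a cohort
(5-year birth block × sex × birth place).  The cohort AD death rate r_c is
the proportion of cohort members whose death record carries an AD code; the
package takes that boolean as input (an ICD mapping is a thin input utility,
never re-derived).  For a pedigree with n_c blood descendants in cohort c,

    E = Σ_c n_c r_c,   RR = O / E,   p = P(X ≥ O),  X ~ Poisson(E).

The Poisson form approximates the true sum of per-cohort binomials; it is
slightly conservative (the binomial sum is underdispersed), increasingly so
as rates grow.  Marry-in spouses carry no founder descent and are excluded
from both O and E; individuals with unknown birth year are excluded from
rate denominators and expectations symmetrically, with counts logged.

**High-risk** is operationalized as RR > 1 and p < α (default α = 0.05,
configurable; a Bonferroni-across-pedigrees switch exists but is off by
default).  Study-pedigree selection additionally requires ≥ 4 resilient
members and ≥ 4 AD cases.

Because the test statistic is discrete, its exact size is below the nominal
level and oscillates with E (≈ 0.03–0.05 for E in 5–50).  The calibration
benchmark therefore checks the empirical null rejection rate both against
α (validity: never above) and against the mean exact size computed from the
Poisson tail at each pedigree's E (sharpness).  Comparing a discrete test's
rejection rate to nominal α alone would fail any correct implementation.

## Parametric linkage

The trait model is a single-locus dominant model: disease (here: protective)
allele frequency q = 0.005, penetrance 0.5 for carriers and 0.0005 for
non-carriers, both configurable, with a recessive switch.

The pedigree likelihood at recombination fraction θ between trait and one
marker is exact.  Each individual's latent state is an ordered pair of
two-locus haplotypes (trait allele × marker allele; 16 states for a SNP).
Founders draw haplotypes at Hardy–Weinberg and linkage equilibrium; a parent
transmits a haplotype by choosing a grandparental origin at the trait locus
(½ each) and recombining to the marker with probability θ; penetrance applies
to the trait genotype, a genotype observation is an indicator on the marker
pair, and unknown phenotypes contribute a factor of one.  The joint sum over
latent states is computed by variable elimination on the pedigree's Bayes
network with a min-degree order — a generalized Elston–Stewart peeling exact
for arbitrary zero-loop pedigrees (and for looped pedigrees up to 12 members;
larger looped structures raise an explicit error).  Factors are rescaled
after every elimination so deep pedigrees cannot underflow, and a
Mendelian-inconsistent configuration yields a −inf log-likelihood flag rather
than silent underflow.  A brute-force enumeration over all genotype
assignments (depth-first with zero-branch pruning, scalar arithmetic,
independent of the elimination engine) is kept as a reference path; the two
agree to ~1e−13 relative on random pedigrees.  Enumeration cost is 16^n, so
reference comparisons use pedigrees of ≤ 10 members.

The reported score is the two-point TLOD, max over a θ grid
({0, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5} by default) of
log10 L(θ)/L(0.5); the grid must contain 0.5 so the score is ≥ 0 and exactly
0 for uninformative data.  This two-point exact statistic stands in for an
MCMC multipoint TLOD: the sampler behind that statistic is a method
substitution documented here, with the enumeration equivalence as the
ground-truth contract.  Thresholds: > 1.86 suggestive, > 3.30 significant
(the conventional genome-wide false-positive calibration for this design).

**Support intervals.**  Two-point TLOD profiles are jagged: a marker whose
key meioses happen to be uninformative in the family (homozygous parents)
scores near zero even inside a linked region.  The 1-LOD support region is
therefore the run of markers within 1 unit of the maximum around the argmax,
bridging runs of fewer than `merge_gap` (default 3) sub-threshold markers —
the same rule merges adjacent peaks — and the reported genomic interval
extends to the first flanking marker beyond the run on each side, because
the 1-LOD crossing lies between that marker and the last in-support one.

**Marker panel pruning** keeps markers with observed heterozygosity ≥ 0.3
and pairwise r² ≤ 0.5 against already-kept markers inside a trailing
50-marker window, estimated from founder genotypes (all members with a
warning when founders are untyped).

## Variant-filter cascade

Seven rules in fixed order, each recording pass / fail / not-applicable per
variant; a variant is retained iff no rule fails (the conjunction is
order-independent, so the trace order is presentational — except
compound-heterozygote detection, which depends on which other variants
survive and is deliberately evaluated last within the zygosity rule).
Conventions:

- reference-panel frequency ≥ 3% in any panel excludes; absent frequency
  passes (a novel variant cannot be excluded on evidence it lacks);
- "shared by resilient samples" defaults to *all* sequenced resilient
  members, relaxable via `min_resilient_sharing`;
- the conservation criterion is encoded literally as phyloP p ≥ 0.01 with
  the comparator configurable (`phylop_conserved_if_geq`), since the
  inclusion direction of a conservation p-value is ambiguous in the source
  criterion;
- a seed gene is proximal to itself (path length 0) by default
  (`seed_is_proximal`);
- absent annotations make a predicate not-applicable; in lenient mode
  (default) the variant passes that rule, in strict mode it fails;
- variability blacklists (top 0.2% windows, top 1% genes) are inputs, not
  recomputed; BED inputs are 0-based half-open and converted to the 1-based
  internal convention at parse time.

Capture harmonization keeps variants inside the intersection of all supplied
capture BEDs.  Genotype reassignment follows three rules: keep a call that
passed quality filters; set to missing when a failed/uncalled site still has
alternate-supporting reads; set homozygous reference only when every read is
reference — so reassignment never erases alternate-allele evidence.

## Association

Single-variant tests are additive-coding logistic regressions (maximum
likelihood via IRLS, through statsmodels) with age, sex and site covariates;
genotypes are oriented to the control-sample minor allele before fitting.
Because the design screens for protection, the one-sided p is Φ(β/SE).
Perfect separation raises an explicit error with an optional ridge fallback.
The crude 2×2 allelic OR (Haldane–Anscombe 0.5 correction on zero cells,
flagged; Woolf CI) is the descriptive companion.

The gene-based statistic is the burden/kernel family: with null-model
residuals r = y − μ̂ (covariate-only logistic fit), per-variant scores
s_j = G_jᵀ r and weights w_j = Beta(MAF_j; 1, 25),

    Q_ρ = (1 − ρ) Σ_j w_j² s_j² + ρ (Σ_j w_j s_j)²,
    ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.

The observed statistic is the minimum over ρ of the permutation p of Q_ρ;
its overall p comes from permuting the residual vector, recomputing the
min-p statistic for every permutation (rank-based, one shared permutation
pool), with p = (1 + #{perm ≥ obs})/(n_perm + 1), bounded below by
1/(n_perm + 1).  This permutation min-p replaces the analytic
quadratic-form tail of the original statistic family: it removes the
distribution machinery while preserving the statistic, at Monte-Carlo
resolution set by n_perm.

## Differential expression

Per-gene OLS of normalized log-scale expression (normalization is upstream;
the module consumes the matrix) on diagnosis (control = 0, AD = 1, so
positive β = up in AD) plus covariates.  The comprehensive model adds the
five CNS marker channels, standardized (coefficients per SD of marker
signal; raw-scale entry is a switch), with constant channels dropped so the
model collapses exactly onto the simple one when composition carries no
signal.  Rank-deficient designs flag every gene rather than crash; residual
degrees of freedom are n − rank(X) and asserted per fit.  Multiple testing
uses Storey q-values (λ grid 0–0.95 step 0.05, cubic π₀ smoother evaluated
at the largest λ) with a Benjamini–Hochberg fallback for fewer than 100
genes, where the π₀ fit is unstable.  The replication path log-transforms
expression and fits an ANCOVA with age and sex; constant covariates are
dropped so the model nests exactly down to a two-sample t-test.

## Assay statistics

%Cytotoxicity = (transfected − spontaneous)/(maximum − spontaneous) × 100
(affine-invariant in the three readings).  Comparative-Ct: ΔCt = mean target
Ct − mean housekeeping Ct per condition, fold = eff^(−ΔΔCt) with the
amplification efficiency defaulting to 2.0 (perfect doubling) and
per-assay override; the "20% standard-error" exclusion is interpreted as the
replicate-mean SE relative to the mean (CV ≤ 20%, configurable denominator);
the fold SE is the delta-method propagation of the four replicate-mean
variances.  ELISA values normalize to total protein (pg/µg).  Group
comparisons run one-way ANOVA and, only when it rejects at 0.05,
equal-variance t-tests against the control group (vs-control rather than
all-pairs by default, matching the experimental layout) with the Bonferroni
multiplier equal to the number of comparisons performed, capped at 1.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (spec, seed) and every dataset ships
with machine-readable truth.

- **Genealogies**: founder couples, Poisson(2.7) offspring per couple over
  6 generations by default, marry-in spouses, birth years 1850–1960,
  90% in-state.  AD mortality is Bernoulli per cohort hazard (default 0.05)
  for everyone; designated high-risk pedigrees multiply the hazard of blood
  descendants by the spike RR (truncated at 1).  Resilient labels are drawn
  at rate 0.12 among non-AD members.  These sizes make pedigree expected
  counts E ≈ 10–25 so the discrete Poisson test's size is near nominal.
- **Gene drop**: forward simulation of the exact generative model the
  likelihood integrates over — founder haplotypes at linkage equilibrium,
  per-meiosis trait-locus origin, per-marker recombination at that marker's
  θ to the trait.  Markers are conditionally independent given the trait
  origin; there is no background LD beyond that, so pruning tests use
  explicitly constructed correlated pairs.
- **Variant tables**: each of the seven rules' outcomes drawn independently
  (configurable pass fractions), annotations constructed to realize each
  outcome, one gene per variant so compound-het rescue never blurs truth;
  retained truth is the conjunction.
- **Case-control**: genotypes Binomial(2, MAF) per group (defaults match
  the replication design, 544/3605 at MAF 0.031/0.045), age/sex/site
  covariates, with an off-by-default age-per-allele confounding switch.
- **Expression**: log-scale baseline + diagnosis effect + covariate effects
  + marker-channel loadings + Gaussian noise (σ = 0.3); diagnosis effects
  routed through marker channels create the mediation scenarios the
  comprehensive model is meant to absorb.

What passing tests on these data do **not** show: robustness to real LD
structure, genotyping error, pedigree misspecification, censored mortality
ascertainment, count-level expression noise, or population stratification —
none of which the generator emulates.

## Problem sizes used by the validation benchmarks

Poisson exactness on E ≤ 50, O ≤ 100 (tolerance 1e−12) and null calibration
on 1,000 generated pedigrees; peeling-vs-enumeration on 100 random pedigrees
of 3–8 members (rel. 1e−9; enumeration is 16^n); null scans 200 × 100
markers on 22-member pedigrees; localization power 100 replicates on
30-member pedigrees conditioned on ≥ 10 doubly informative meioses
(carrier parent heterozygous at the linked marker); logistic null 500
replicates at n = 2,000; gene-test null 200 replicates at 499 permutations;
OR recovery 200 replicates at 544/3605; DGE FDR 20 replicates of 1,000
genes and recovery 200 replicates at 80 vs 76.  All seeds derive from one
`--seed` via `numpy.random.SeedSequence`.

## Known limitations

- Two-point linkage only: no multipoint inheritance-vector HMM, no X-linked
  models, no haplotype reconstruction output.
- Exact likelihood for looped pedigrees is limited to ≤ 12 members.
- The gene test's resolution is bounded by the permutation count.
- The candidate-variant fixture encodes annotation dimensions absent from
  its source table at their known post-filter state; it is a regression
  fixture for the cascade's conventions, not an annotation ground truth.
- Pedigrees are treated independently throughout; individuals appearing in
  several founder-defined pedigrees are not deduplicated.
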