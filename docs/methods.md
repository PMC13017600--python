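# Methods

`kinmethyl` analyses how the kinship between an individual's parents is
reflected in its methylome and in methylation-based estimates of its age.
The package was built around a captive deer-mouse (*Peromyscus*) colony
setting — closed, randomly bred, with complete pedigrees and a conserved-CpG
methylation array — but every component operates on generic inputs: a
pedigree table, a CpG-by-sample beta matrix with genomic annotation, and
per-sample metadata.

## Pedigree kinship and the relatedness score

The kinship coefficient phi(i, j) is the probability that random alleles
drawn from i and j are identical by descent.  It is computed by the
classical tabular recursion over a topologically sorted pedigree
(phi(i,i) = (1 + phi(father, mother))/2; phi(i,j) = (phi(father,j) +
phi(mother,j))/2 for j preceding i), with founders assumed non-inbred and
mutually unrelated.  Individuals with one unknown parent are treated as
founders and flagged, rather than silently propagating a half pedigree.

An animal's **parental relatedness score** is phi(sire, dam) on a
configurable scale.  The default is the parents' relationship coefficient
in percent, 2·phi·100 (full-sib parents → 50), chosen because published
effect sizes on this trait (slopes near 1e-3 per unit, signature RMSE
near 3) are only plausible on a percent-like scale; `phi` and `2phi`
scales are available.

A gene-dropping Monte-Carlo estimator (`gene_drop_kinship`) simulates
allele transmission through the pedigree and estimates IBD probabilities
directly.  It shares no code with the recursion and serves as the
independent oracle in the test suite: across random pedigrees,
approximately 99.7% of pairwise deviations must fall within three Monte
Carlo standard errors, the statistically correct reading of "agrees within
3 SE" when hundreds of pairs are compared at once.

## Synthetic colony and methylome

The generator is first-class, tested code that defines the study
conditions for every downstream check.

**Colony.** Founders (default 20) are bred for 6 generations, 15 pairs per
generation drawn from the two preceding generations; litter sizes are
1 + Poisson(3).  A fraction of pairings (default 0.1) are full-sib matings,
reflecting the inevitable pairing of relatives in a closed colony under
rotational breeding; this keeps the cohort's parental-relatedness gradient
wide (0 up to and beyond the full-sib level of 50, occasionally ~100 for
matings between already-inbred sibs, matching the high-relatedness
outliers such colonies produce).  The study cohort is 96 animals (47
female, 49 male) sampled across offspring generations; ages at sampling
are uniform on 1.3–33 months, independent of pedigree depth.

**Array.** CpGs (default 5,000; a desk-scale stand-in for a ~37k-probe
mammalian array) are placed uniformly over 24 synthetic 100-Mb
chromosomes (1–23 and X); only relative densities matter for the
enrichment statistics, so uniform lengths are sufficient.  16.3% of CpGs
are flagged as CpG-island probes, matching the array-wide share implied by
a ~84% outside-island background.  CpG placement, baselines and planted
effects are drawn from a fixed `array_seed`, separate from the cohort
seed, so different simulated cohorts share CpG biology exactly as real
cohorts profiled on one platform do.

**Planted effects.**  On the logit scale,

    logit(mu_ij) = b0_j + s_j·(Age_i − mean Age) + r_j·m_i·Rel_i + g_j·Male_i

with four disjoint CpG classes: *clock* CpGs (350) with age slopes of
random sign, |s| ~ U(0.02, 0.08) per month; *relatedness* CpGs (250) with
per-percent-unit effects |r| ~ 0.02·U(0.7, 1.3), positive with probability
0.8 (the hypermethylation bias), magnified 2× in males (m_i); *sex* CpGs
(150) with offsets ±0.8·U(0.7, 1.3); the remainder null.  The 0.02
per-unit default gives planted effects a noncentrality of roughly 6–9 at
n = 96 given the Beta noise below — strong enough that an EWAS should
recover ≥90% of them at FDR 0.1, which is the regime the published
discovery counts imply.  Half of the relatedness CpGs also carry an age
slope whose sign *opposes* their relatedness effect: relatedness pushes
these CpGs toward their "young" methylation state.  This is the planted
mechanism by which parental relatedness reads as epigenetic age
deceleration, mirroring the compensation interpretation (relatedness-driven
hypermethylation offsetting age-related demethylation).

Relatedness CpGs are depleted on X (weight 0.15) and enriched on
chromosome 4 (weight 2.5); 40 of them are packed into a single 2-Mb window
on chromosome 7 (60–62 Mb), the planted sub-chromosomal cluster.

**Noise.**  Observed betas are Beta-distributed around mu with
concentration nu_i = 30 / (1 + 0.02·Age_i).  The age-dependent denominator
is the epigenetic-drift term: older animals have noisier methylomes, which
is what the entropy module detects.  Concentration 30 rather than a larger
value keeps the surrogate clock's accuracy and the size of the emergent
relatedness→EAA effect in the regime the study system reports (clock
r ≈ 0.99, relatedness explaining on the order of 10% of residual EAA
variance) — with much tighter noise the clock becomes near-perfect and the
EAA effect vanishes into numerical residue.  A 1% missing-completely-at-
random mask emulates probe masking; per-CpG models drop missing samples.

`SimConfig.null()` defines the exchangeable global null used for type-I
calibration: no relatedness effects *and* age-independent noise.  The
drift term is excluded there deliberately: it makes errors heteroskedastic
across samples, and the homoskedastic LRT's extreme tail then inflates
(measured: the per-seed probability of at least one false BH discovery
roughly doubles).  That inflation is a property of the test under
heteroskedasticity — a known limitation that applies equally to real data,
documented here rather than hidden in the calibration check.

**What the generator does not emulate.**  Probe-level intensity artifacts
and normalization residue, cell-composition structure, genome-wide
correlation between neighbouring CpGs (outside the one planted cluster),
realistic chromosome lengths, and bimodal genome-wide beta landscapes.
Passing tests therefore demonstrate that the statistics do what they claim
under their stated assumptions, not that the biological effect sizes of
any real cohort will match.

## EWAS by likelihood-ratio test

Each CpG is fitted with nested Gaussian linear models (beta values as the
response; an optional logit/M-value transform is off by default):

    reduced:  beta = b0 + b1·Age + b2·Male
    full:     reduced + b3·Relatedness

The LRT statistic is n·log(RSS_reduced/RSS_full), i.e. twice the
difference of maximized Gaussian log-likelihoods with variance MLEs.
P-values come from the statistic's **exact** finite-sample null
distribution: under Gaussian errors the LRT is a monotone function of the
partial F statistic, so p = P[F(1, n−k) > (e^{LRT/n} − 1)(n − k)].  The
asymptotic chi-square(1) reference is anti-conservative at n ≈ 100
(measured null rejection 0.056–0.061 at nominal 0.05); the exact reference
restores calibration (measured 0.049–0.051) while leaving the statistic
itself untouched.  Sex is coded F=0, M=1; swapping the coding flips b2's
sign only.  CpGs need ≥10 non-missing samples; constant CpGs are flagged
degenerate (p = 1).  CpGs sharing a missingness pattern are fitted
together, so complete matrices run as single matrix operations.

Benjamini–Hochberg q-values are computed over testable CpGs by the
standard step-up rule (verified against an independent implementation).
Sex-stratified reruns drop the sex column and compute BH within the
stratum, as the stratified discovery counts are reported per sex.

## Surrogate clock, corrected age, EAA

The clock is an elastic-net regression (l1_ratio 0.5, penalty by internal
cross-validation) of chronological age on betas — the same model family as
published mammalian clocks, but trained on synthetic data; published clock
weights are out of scope, and externally computed DNAmAge columns are
accepted as input.  Out-of-fold predictions (penalty refitted per fold)
provide the honest accuracy estimate.  In the pipeline the clock is
trained on an *independently simulated reference colony* and applied to
the study cohort: an age predictor trained on the cohort it evaluates
partially absorbs any relatedness signal into its fit, whereas the real
workflow (and the planted effect) requires the clock to come from other
animals.

Derived quantities: CorrectedAge = DNAmAge · (mean Age / mean DNAmAge);
residual age = corrected age − chronological age; EAA = residuals of OLS
DNAmAge ~ age + sex (exactly orthogonal to both covariates by
construction).

The EAA-on-relatedness regression reports OLS with conventional and HC3
standard errors, Huber M-estimation (tuning constant 1.345, IRLS,
tolerance 1e-8, ≤100 iterations), the partial R² and added-variable
coordinates from double residualization on age + sex (slope identical to
the multivariate OLS slope), and the leave-one-out slope distribution.

## Methylome entropy

Sample-level Shannon entropy of the beta distribution: a Gaussian KDE on a
512-point grid over [0, 1] with boundary reflection at 0 and 1 and
renormalization, then Ĥ = −Σ f log f Δx.  The grid plug-in form was chosen
for determinism; a leave-one-out resubstitution estimator is available
(`estimator="loo"`).  Bandwidth is Silverman's rule floored at 0.005 to
avoid degenerate spikes.  Uniform(0,1) data scores ≈0 nats (the analytic
value); concentrated bimodal beta landscapes score below diffuse mid-range
ones.  Associations are plain linear models: R² for entropy ~ age and
partial R² (double residualization on age + sex) for EAA and relatedness.
Note that with strong planted relatedness effects on 5% of CpGs the
generator *does* induce an entropy–relatedness association; the near-zero
partial R² reported for real data reflects far sparser effects relative to
a 37k-CpG array.

## PCA and causal mediation

PCA is computed on the column-centered sample × CpG matrix (CpG-mean
imputation for the 1% missingness), with each component's sign fixed so
its largest-magnitude loading is positive.  Per-PC associations are linear
models PCk ~ predictor; the joint (PC1, PC2) test uses MANOVA's Pillai
trace (for a single component it reduces exactly to the univariate F
test).

Mediation of the relatedness→EAA effect through a PC score uses two
linear models — M ~ T + age + sex and Y ~ T + M + age + sex — and the
product-of-coefficients decomposition: ACME = a·b, ADE = c′,
total = c′ + a·b (exact identity in the linear no-interaction case).  Age
and sex enter both sub-models; this is the conservative superset given
that EAA is already age/sex-adjusted.  Uncertainty comes from
nonparametric case-resampling of the full two-model fit (default 10,000
draws, percentile CIs, bootstrap p = 2·min(frac ≤ 0, frac ≥ 0)); the
bootstrap is vectorized over replicates via batched normal equations.
Sensitivity to unmeasured mediator–outcome confounding uses the linear
structural-equation result ACME(ρ) = a·(s2/s1)·(r12 − ρ·sqrt((1 −
r12²)/(1 − ρ²))), where s1, s2, r12 are residual SDs and the residual
correlation after regressing M and Y on T and covariates; ACME(0) equals
the unadjusted estimate and the curve crosses zero exactly at ρ = r12.
Sex-stratified runs repeat the procedure per sex (minimum 20 samples,
otherwise skipped with a warning) with BH across mediators within sex.

## Genomic enrichment

Chromosome level: 2×2 tables (significant/non-significant ×
on/off-chromosome) at FDR < 0.1, two-sided Fisher exact tests (depletion
was as interesting as enrichment in the motivating analysis), BH across
chromosomes, and uniformity-expected counts K·assayed_c/N.  Window level:
non-overlapping 2-Mb tiles (0-based half-open; a `step_bp` option gives
true sliding windows), upper-tail hypergeometric test of the window's
significant count against the genome-wide rate at FDR < 0.05, BH across
windows containing at least one assayed CpG, and gene lists for the
significant CpGs inside enriched windows.  At the 5,000-CpG desk scale the
chromosome-level Fisher test is underpowered: the planted X depletion and
chromosome-4 excess reproduce in direction but usually not at q < 0.05;
detecting them at the significance levels reported for a full 37k array
requires the full array.  The planted 2-Mb cluster, by contrast, is
recovered as the top window in essentially every seed.

## Relatedness signature

Three stages: (1) keep CpGs with EWAS FDR < 0.05; (2) LASSO with 10-fold
CV, keep nonzero coefficients; (3) 80/20 sample split, elastic net
(l1_ratio 0.5, penalty by CV on the training split), RMSE and R² on the
held-out 20%.  Stages 1–2 run before the split, exactly as the published
procedure describes; because the selection stages see all samples, the
held-out metrics are mildly optimistic, and a `strict_split` mode repeats
selection inside the training split only for a leakage-free estimate.
Predictors are standardized internally; coefficients are reported on the
beta scale.  On the default generator the pipeline selects a few dozen
CpGs and reaches held-out R² around 0.9–0.96 across seeds; a calibrated
sparse-signal design (noise at 5% of response variance) is provided for
controlled benchmarking, where R² ≈ 0.95 and label-permuted controls fall
to ≈0.

## Pipeline and determinism

`run_pipeline` executes simulate → kinship → EWAS → clock/EAA → entropy →
PCA/mediation → enrichment → signature from one YAML-serializable config.
Every stochastic stage takes an explicit seed; outputs are plain-text
tables and JSON with fixed float formatting; a manifest records per-stage
timing, parameters and SHA-256 hashes of every output, and reruns under an
identical config are bit-identical.  Problem sizes used in the shipped
checks (5,000-CpG default; 2,000 CpGs × 100 seeds for null calibration;
600 CpGs × 100 seeds for entropy power; 1,200 CpGs for the determinism
rerun; 1,000–10,000 bootstrap draws) were chosen so each check completes
in seconds to a few minutes on one CPU while keeping the cohort size at
the study's n = 96.

## Known limitations

* Gaussian LRT on bounded beta values: calibrated in the bulk and tail
  under iid noise, but heteroskedasticity (e.g. age-dependent dispersion)
  inflates the extreme tail; M-values or robust EWAS variants would be the
  remedy on real data.
* The surrogate clock shares no weights with any published clock; clock-
  dependent numbers are not comparable across datasets.
* Pedigree kinship only: no SNP-based relatedness, runs of homozygosity,
  or inbreeding estimated from genotypes.
* Chromosome-level enrichment is underpowered at desk scale (see above).
* Mediation assumes linear, no-interaction models and sequential
  ignorability; the sensitivity curve quantifies, but cannot remove, the
  latter assumption.
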