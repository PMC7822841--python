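# Methods

This note documents the models, parameter choices and numerical decisions
behind `prscreen`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Genotype model

Genotypes are biallelic dosages in {0, 1, 2}. Each individual's two
haplotypes are independent draws of a latent Gaussian vector with AR(1)
correlation `ld_rho` along each LD block, thresholded at Φ⁻¹(p_j) so the
marginal allele frequency is exact and Hardy–Weinberg proportions hold by
construction. This gives LD that is tunable and measurable (empirical r²
between neighbours rises monotonically with `ld_rho`, reaching ≈0.35 at a
latent correlation of 0.9 — thresholding attenuates the latent correlation)
while remaining fast: no coalescent machinery, no recombination maps.
Blocks span ≈100 kb with 1 Mb between block starts, so the default ±250 kb
clumping window never straddles blocks; positions are on one chromosome.

Population structure follows Balding–Nichols drift: subpopulation
frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency
drawn uniformly from `maf_range` (default 0.05–0.5). A Hudson-type
frequency-variance estimator recovers F within ±0.03 at 1000 SNPs.

What this does *not* emulate: realistic human LD decay, allele-frequency
spectra, imputation uncertainty, genotyping batch effects, or
chromosome-scale coordinates. Tests passing on this generator show the
*analysis machinery* is correct and calibrated, not that the pipeline is
robust to every artefact of real array data.

## Disorder model

Liability is standardised to unit variance: a genetic score over `n_causal`
SNPs scaled to variance `h2_liability` (default 0.3), plus
scenario-specific contributions, plus a Gaussian residual that tops the
total up to 1. Cases are liabilities above Φ⁻¹(1 − prevalence); prevalence
defaults to 0.01 (a schizophrenia-like disorder). The recorded diagnosis
can misclassify a fraction of true cases as unaffected
(`misclassification_rate`, default 0 — the rate real cohorts suffer is
unknown, so it is a free parameter); the true status is retained for
oracle checks.

Medication is sampled among diagnosed individuals with probability
`expit(medication_prob_slope × (liability − median case liability))`.
Centring at the case median makes roughly half of cases medicated — a
realistic treated fraction at a baseline interview — while keeping medication
probability increasing in liability, so medicated cases have higher mean
liability (and hence higher PRS) than non-medicated cases. Medication
optionally shifts the trait additively (`medication_trait_shift`), the
simplest mechanism for a drug side-effect that reverses a genetic trend.

## Trait scenarios

* `null` — standard-normal noise, independent of everything.
* `pleiotropy` — a latent mediator with its own causal SNP set
  (heritability `mediator_h2` = 0.5) feeds both the trait
  (`trait_effect` × mediator) and liability: horizontal pleiotropy.
* `structure` — the trait mean is offset per subpopulation
  (`env_gradient`); optionally the same environment also offsets liability
  (`env_liability_gradient`), which is what makes location confound a
  discovery GWAS and hence the PRS.
* `disorder_to_trait` — the trait is shifted by `trait_effect` in true
  (pre-misclassification) cases only.
* `trait_to_disorder` — the trait is heritable (`trait_h2` = 0.3) and
  contributes `trait_effect` × trait to liability; its causal SNPs overlap
  the disorder's direct set (`trait_overlap` = 0.5).

Per-SNP *total* liability effects (direct plus mediated) are stored with
the variant metadata: that is the quantity a discovery GWAS of the disorder
estimates, so oracle summary statistics are consistent with the generating
causal structure.

## Summary statistics

`oracle` mode converts per-allele liability effects to log odds ratios with
the first-order factor φ(t)/(K(1−K)) and adds Gaussian noise with the
standard error implied by a nominal discovery study (default 100,000
individuals, 25% cases — a consortium-scale case-control design). Null SNPs get
uniform P-values by construction. `cohort_gwas` mode runs an actual per-SNP
logistic regression (vectorised Newton–Raphson) on an independent simulated
discovery cohort; for structure experiments the discovery cohort is an
independent half-split of the same population, so stratification bias is
shared with the target while individuals are not.

## Quality control

Filters use the conventional strict inequalities: variant missingness
> 0.02, MAF < 0.01, Hardy–Weinberg 1-df chi-square P < 10⁻⁸ (no continuity
correction; an exact test is unnecessary at that threshold), sample
missingness > 0.01, kinship ≥ 0.088 (third-degree cutoff). The
missingness/MAF pair is applied as independent removal rules; a
`conjunctive` switch selects the literal both-must-fail reading.

Kinship is the KING-robust moment estimator
(N_het,het − 2·N_opposite-homozygote) / (N_het(i) + N_het(j)), restricted
per pair to mutually non-missing variants; a fallback (half the
standardised genomic relationship) is provided. Both give ≈0.5 for
duplicates and ≈0 (unbiased) for unrelated pairs. Pruning removes one
member per flagged pair, greedily dropping the sample in the most pairs
(ties by sample order). **Scale caveat**: at a few hundred synthetic
variants the estimator's per-pair noise (SD ≈ 0.7/√m_effective) makes a
fixed 0.088 threshold flag a visible fraction of unrelated pairs; the
threshold is calibrated for the ~500k-marker panels of real pipelines.
Synthetic cohorts with ≥2000 variants behave well.

PCA standardises columns by √(2p(1−p)) (Patterson convention; sample-SD
scaling by flag), mean-imputes missing calls, drops zero-variance columns,
and fixes each component's sign by making its largest-magnitude loading
positive. Ancestry clustering is k-means (k=4, 10 restarts, fixed seed) on
PC1–PC2, keeping the largest cluster; on a homogeneous cohort this
arbitrarily splits one blob and retains ≈40% — the method's honest
behaviour when its premise (a dominant ancestry cluster plus outgroups)
does not hold.

## PRS construction

Harmonisation joins on SNP id, flips the sign when the effect allele is the
target's other allele, drops strand-ambiguous A/T and C/G pairs (default
on) and duplicate ids, and errors rather than silently scoring nothing.
Scored contributions use the effect-allele dosage exactly (2 − d for
flipped SNPs), so recoding any SNP's counted allele leaves standardised
scores unchanged to floating-point precision.

Clumping is greedy: most significant unclaimed SNP (ties by P, then bp,
then id) claims all unclaimed same-chromosome SNPs within ±250 kb at
r² ≥ 0.1, computed from the target dosages. The ±window (500 kb total span)
follows the PLINK/PRSice convention. An exhaustive brute-force restatement
of the same definition, written independently, agrees exactly on hundreds
of random LD instances.

Missing dosages are imputed with twice the sample effect-allele frequency.
The inclusion threshold is fixed at P < 0.05 (best-fit) — no in-target
threshold search, avoiding overfitting semantics — and P < 5×10⁻⁸ or an
explicit sentinel-id list for the GW-significant profile.

## Screening, quantiles, migration

Association fits are covariates-only vs covariates+PRS; incremental
variance explained is ΔR² (linear) or ΔNagelkerke pseudo-R² against a
shared intercept-only null (logistic). Missing data are deleted listwise
per trait; logistic separation/non-convergence yields a flagged result.
Multiplicity: plain Bonferroni over the screened traits plus the fixed
stringent 10⁻⁷ tier; no FDR layer.

Quantile bins are rank-based equal counts (sizes differ by ≤1, ties broken
by stable sample order); the trend regression uses one-hot bin indicators
with the 11th bin omitted — its coefficient is identically zero, and with
no covariates each linear coefficient equals the bin-mean difference from
the reference exactly. The reference choice only shifts all coefficients by
a constant. Case groups enter the *same* regression as extra factor levels.
Concordance is operationalised (the original call was made by inspecting
plots): trend direction is the sign of the least-squares slope of bin
coefficients on bin index; a case group is concordant iff its coefficient
shares that sign, and everything is "flat" when the slope is not nominally
significant (P ≥ 0.05). Confidence intervals are 95% Wald throughout.

Migration distance is the planar Euclidean distance rounded to the nearest
kilometre (round-half-to-even). District polygons are abstracted to a
regular raster with half-open cells (boundary points belong to the
lower-left rule cell); any object with the same `lookup` interface — e.g. a
polygon gazetteer — can substitute. Density change is current − birth, so
moving somewhere less dense is negative. Follow-up regressions run under
two covariate tiers (age+sex; +deprivation+education) and report the
attenuation ratio beta_extended/beta_base.

## Numerical and design notes

* Determinism: everything flows from one `numpy` Generator seeded by the
  config; identical config ⇒ bit-identical cohort and outputs.
* The structure-confounding experiment compares mean |beta| with and
  without PC adjustment across replicates rather than per-replicate ratios:
  when a PRS is nearly collinear with the structure axis, the adjusted
  coefficient's denominator (residual PRS variance) is tiny and
  per-replicate ratios are wildly unstable. The scenario is configured so
  the PRS carries genuine genetic signal plus a moderate stratification
  component, the regime in which PC adjustment is meaningful.
* The effect-recovery check compares the estimated PRS-trait slope against
  a closed-form population value: dosage covariances under the
  thresholded-AR(1) model are exact bivariate-normal orthant
  probabilities, so the only discrepancy is sampling error and the
  2-standard-error coverage is nominal (~95.4%).
* Problem sizes in the test suite (cohorts of 2,000–20,000 individuals,
  60–1,000 variants, 20–200 replicates) were chosen so each experiment's
  statistical check has comfortable power while the whole suite stays
  interactive on one CPU.

## Known limitations

* The generator's LD, frequency spectrum and geography are stylised; no
  claim is made about robustness to real-array artefacts (batch, call-rate
  structure, sex chromosomes — all out of scope).
* Liability-scale R² for binary traits is offered only via the Nagelkerke
  convention; attributing observed-scale variance to liability requires
  prevalence assumptions not modelled here.
* The kinship threshold's behaviour at small marker counts (above) means
  the end-to-end pipeline on tiny synthetic panels over-prunes relative to
  a real 500k-marker run.
* Medication effects are additive trait shifts; dose, duration and
  indication-by-severity confounding are not modelled, so the medicated
  vs non-medicated contrast should be read qualitatively.
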