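# Methods

This note records the models, parameter choices and numerical conventions
behind `transprs`, and what the synthetic-data-driven tests do and do not
demonstrate about real data.

## Score model and standardization

A PRS is `Σ_k β_k x_k` over effect-allele dosages `x_k ∈ [0,2]`. Scores are
standardized by dividing by the control SD within each stratum (study or
genotyping batch) and are *not* centered: standardized means remain
comparable across scores and groups, which the calibration analysis relies
on. Missing dosages are mean-imputed at scoring time, with `2·eaf` from the
weight file when it carries frequencies, otherwise the observed column
mean. Strand-ambiguous variants (A/T, C/G) are dropped during allele
harmonization rather than resolved by frequency matching — safer, at the
cost of a few variants. Positions are 1-based; windows are
`|pos_i − pos_j| ≤ w` on the same chromosome.

## Clumping and thresholding

Stage 1 removes near-duplicates (r² > 0.9 within 1 Mb, lowest association
P value retained); stage 2 greedily clumps in ascending P (a variant is
kept iff no kept variant within 250 kb has r² > 0.1 with it). Both stages
share one greedy routine; ties in P break by (chromosome, position), which
makes the output invariant to input row order. r² comes from a genotype
reference panel, computed on demand; variants absent from the panel are
treated as uncorrelated with a warning.

Threshold selection evaluates validation AUC at the observed P values in
`[p_min, p_max]` (defaults 5×10⁻⁸ and 10⁻³). Because the selected set — and
hence the score and its AUC — changes only when the threshold crosses an
observed P value, this is *exactly* equivalent to any denser grid (for
instance steps of 10⁻¹⁰), not an approximation; the tests verify the
equivalence against a dense grid directly. AUC ties break toward the
smaller threshold (fewer variants). Scores are accumulated incrementally as
variants enter, so the grid search is O(n·m) overall.

## Joint (LD-adjusted) weights

Marginal GWAS effects are inflated by LD. On the standardized-genotype
scale (where the LD matrix is a correlation matrix and effects are
scale-consistent) the joint effects solve `R γ′ = β′`; dosage-scale weights
divide by `√(2p(1−p))`. The solve is a symmetric `linalg.solve` of
`R + εI`; the ridge `ε` defaults to 10⁻³ because a panel-estimated `R` from
a few hundred genotypes is ill-conditioned at high LD; `ε = 0` is exact for
well-conditioned `R` and is what the round-trip tests use. A singular
system without ridge raises an error that suggests the ridge.

Allele-frequency source for all `√(2p(1−p))` rescalings: the ancestry whose
weights are being produced (the target ancestry for the EB posterior).

## Empirical Bayes cross-ancestry fusion

Target-ancestry (e.g. East Asian) marginal estimates are unbiased for the
target population but noisy; a European-trained joint estimate is precise
but may transfer incompletely. We model the target standardized effect as
normal around the European value with a *common* heterogeneity variance
`A`, estimated by method of moments,

    Â = max(0, meanⱼ[(β̂′_ASN,j − β′_EUR,j)²] − meanⱼ[se′ⱼ²]),

and report the posterior mean
`β′_EUR,j + Â/(Â + se′ⱼ²)·(β̂′_ASN,j − β′_EUR,j)`. The shrinkage factor
lies in [0,1], so the posterior is always between prior and estimate; the
`se′→0` and `Â=0` limits return the target estimate and the prior
respectively. This normal-normal, common-variance form is this package's
own reconstruction of the approach; per-variant or bivariate priors are a
natural extension hook but are not implemented.

## Combination and evaluation

Combination coefficients are fitted by plain logistic regression of
case/control status on the standardized components — no covariates by
default (a flag adds PCs and stratum indicators), matching how such
combinations are typically fitted on a validation set. "Relative
contribution" of component i is `|α_i|·SD_i / Σ_k |α_k|·SD_k` (the
component's share of the linear predictor's scale); the quantity is not
uniquely defined in the literature, and this variance-scaled convention is
documented rather than canonical. Fitting and evaluating on the same
validation set overfits slightly by construction; the package exposes the
machinery and leaves cross-validation to the caller.

OR per SD comes from logistic regression adjusted for the first 10 PCs and
stratum indicators (Wald CI); HR per SD from a Cox partial-likelihood fit
adjusted for the configured number of PCs (default 2). AUC is always the
score-only rank statistic (ties half-credit), with a DeLong-variance CI;
printed AUC/OR pairings can be checked against the equal-variance binormal
identity `AUC = Φ(ln OR/√2)`. Fixed-effect meta-analysis pools log effects
by inverse variance and reports Cochran's Q with k−1 df; AUCs are pooled
the same way when DeLong SEs are available.

## Absolute risk

Percentile band k (default 100 bands of 1%, supporting top/bottom-1%
readouts) has relative risk
`RR_k = E[e^{βz}|z∈band_k]/E[e^{βz}]`, computed in closed form from the
truncated-normal tilted mean and renormalized so `Σ f_k RR_k = 1` exactly.
The baseline hazard is constrained so that band hazards reproduce the
observed population incidence *among women still unaffected at each age*:
`λ₀(t) = λ_pop(t)·Σf_kS_k(t) / Σf_kS_k(t)RR_k`, updated year by year.

Discretization is an annual-probability recursion over half-open one-year
intervals, `S(t+1) = S(t)(1 − h(t))`, rather than `exp(−h)`. This choice is
deliberate: with linear decrements the f-weighted average of band risks
equals the population risk computed directly from `λ_pop` *identically*
(the tests require 10⁻⁹–10⁻¹⁰ agreement), whereas exponential survival
breaks the identity at O(h²). At annual hazards of order 10⁻³ the
difference from the continuous-time answer is ~10⁻⁵ in cumulative risk.
Competing mortality multiplies in as an independent survival factor,
assumed equal across bands; the incidence/mortality reader accepts any
registry table per 100,000 (whether or not breast-cancer deaths were
removed from the mortality column is the caller's choice; conservation
holds either way). Lifetime risk is computed to age 80; 10-year risks
condition on being unaffected and alive at the starting age. Birth-cohort
projection multiplies incidence by `(1+r)^years` with r defaulting to
3.9%/year.

## Calibration

Percentile maps use control distributions only (cases are risk-enriched).
The normal map is `Φ((μ_s + σ_sΦ⁻¹(p) − μ_t)/σ_t)`, clipped into the open
unit interval where Φ saturates in floating point; an empirical
interpolated-ECDF companion covers non-normal scores. Reported percentiles
round to the nearest integer. `risk_at_percentile` composes the map with a
percentile→lifetime-risk function (band midpoint interpolation of the
absolute-risk curves) and reports own-calibrated risk, reference-calibrated
risk, and their gap; when the population mean is below the reference mean
the gap is negative (systematic underestimation) at every percentile.

## Synthetic data: what it emulates and what it does not

The generator stands in for access-controlled consortium data:

* **Allele frequencies**: Balding–Nichols `Beta(p(1−F)/F, (1−p)(1−F)/F)`
  per ancestry around shared ancestral frequencies; default Fst 0.08 per
  population puts the two populations ~0.15 apart, enough that PC1
  separates them (tests require silhouette > 0.5).
* **Genotypes**: Gaussian-copula haplotypes with block-AR(1) latent
  correlation (default blocks of 10, ρ = 0.35), summed to Hardy–Weinberg
  dosages. Hard calls by default; a `mean_info` option attenuates dosages
  with Beta-distributed per-variant info scores.
* **Summary statistics**: `β′ = Rγ` on the standardized scale plus
  `N(0, 1/√n)` noise (n defaults to 40,000, the scale of a large
  case-control meta-analysis); the noise-free mode is the exact inverse of
  the joint-weight solve, which the round-trip tests exploit.
* **Effects**: sparse (12 causal in 120 variants by default), bivariate
  normal across ancestries with correlation 0.8 — a stand-in for partial
  transferability; no generative model for heterogeneity is established in
  the literature, so this default is a labelled assumption, not an
  estimate.
* **Phenotypes**: case-control sampling uses the rare-disease retrospective
  limit (cases tilted by `e^{βz}`, i.e. N(β,1) for a standard-normal
  score); cohorts use exponential event times with proportional hazards,
  exponential loss to follow-up (1%/year) and administrative censoring at
  15 years. Defaults mirror the study design the pipeline targets:
  validation 6,392/6,638 cases/controls at OR/SD ≈ 1.55; prospective
  cohorts of ~90,000–100,000 women accruing ~1,600 incident cases at HR/SD
  1.62 (baseline hazard 1.1×10⁻³/year).
* **Incidence**: a smooth log-quadratic schedule peaking near age 65 at
  230/100,000/year with Gompertz-like competing mortality — a synthetic
  stand-in shaped like East-Asian registry incidence, not registry data.

Passing tests therefore demonstrate internal correctness (estimators
recover known truth, identities hold, selection matches oracles) — not that
real LD, real effect-size architecture, or real registry rates behave like
the generator. In particular the copula LD has no recombination-map
realism, admixed individuals are not modelled, and the synthetic incidence
schedule should never be quoted as an actual population's risk.

## Problem sizes and determinism

The test suite runs the recovery checks at the sizes the analyses target
(e.g. 100 replicate cohorts of 10⁵ women for Cox CI coverage; 5×10⁵ per arm
for binormal AUC checks) and everything else at small fixture sizes. All
stochastic code takes a seed or `numpy.random.Generator`; the CLI requires
a seed for stochastic stages and writes a manifest with SHA-256 hashes of
every artifact, so a rerun with the same config is byte-identical.

## Known limitations

* The EB specification is a reconstruction (see above); results with other
  prior families may differ.
* No BGEN/PLINK-binary input, no liftover, no multi-allelic sites.
* Combination fitting offers no overfitting correction.
* Absolute-risk bands assume equal competing mortality across PRS bands.
* lassosum- and PRS-CSx-style weight estimation is out of scope; the
  pipeline consumes externally produced scoring files for such PRSs.
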