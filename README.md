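# transprs

Trans-ancestry polygenic risk score (PRS) construction, evaluation and
calibration, built around the analysis pipeline used for breast-cancer risk
prediction in East- and South-Asian populations.

Most large GWAS are European; a PRS trained there transfers imperfectly to
other ancestries, and even a well-transferring score has different
*distributions* across populations, so percentile-based risk communication
breaks without population-specific calibration. `transprs` implements the
full stack needed to study and fix both problems, driven end-to-end by a
synthetic-data generator with known ground truth (the consortium data such
analyses use are access-controlled).

## What it computes

A PRS is the weighted allele-dosage sum

    PRS = β₁x₁ + β₂x₂ + … + β_m x_m

standardized to unit SD in controls, stratum by stratum. The pipeline
covers:

* **C+T (clumping + thresholding)** — two-stage greedy LD pruning (1 Mb /
  r² > 0.9 dedup, then 250 kb / r² > 0.1 clumping, lowest P wins), followed
  by a P-value-threshold grid search over [5×10⁻⁸, 10⁻³] maximizing
  validation AUC. The AUC is piecewise constant in the threshold, so
  evaluating at the observed P values is exactly a dense grid.
* **LD-adjusted joint weights** — on the standardized-genotype scale,
  `γ′ = R⁻¹β′` with `R` the SNV correlation matrix from a reference panel,
  rescaled per variant by `1/√(2p(1−p))` (small ridge for panel-estimated
  `R`).
* **Empirical Bayes cross-ancestry fusion** — a normal-normal model with
  method-of-moments heterogeneity variance `Â` shrinks noisy
  target-ancestry estimates toward a well-powered European prior:
  `post = β′_EUR + Â/(Â+se′²)·(β̂′_ASN − β′_EUR)`.
* **Linear combination** of PRSs, `α₀ + α₁PRS₁ + α₂PRS₂`, with α fitted by
  logistic regression on a validation cohort, plus variance-scaled relative
  contributions.
* **Evaluation** — OR per SD (logistic, PC/stratum-adjusted), HR per SD
  (Cox), AUC by the rank statistic with DeLong CIs, fixed-effect
  inverse-variance meta-analysis with Cochran's Q, and binormal
  consistency checks (`AUC = Φ(ln OR/√2)`).
* **Absolute risk** — percentile-band relative risks from the
  truncated-normal tilted mean, a baseline hazard constrained so band
  hazards reproduce observed population incidence among survivors at every
  age, lifetime/10-year risks with competing mortality, screening-threshold
  crossing fractions, and birth-cohort incidence projection (default
  +3.9%/year).
* **Calibration** — per-ancestry control distributions, normal and
  empirical percentile maps between populations, and the risk gap incurred
  by reading one population's percentile off another's distribution.

## Worked example

Build a two-ancestry study with known effects, run C+T and EB reweighting,
combine, and evaluate (full script in the docstrings; excerpt):

```python
from transprs import synthetic as syn, clumping as cl, weighting as wt
from transprs import scoring as sc, evaluation as ev

scen = syn.two_ancestry_scenario(m=120, n_causal=12, n_gwas=40000, seed=42)
ld = cl.PanelLD(scen.genotypes["EAS"])
dedup = cl.dedup_high_ld(scen.sumstats["EAS"], ld, cfg := cl.ClumpConfig(p_max=1e-2))
kept = cl.greedy_clump(dedup, ld, cfg)
t, ws_ct, curve = cl.threshold_grid_select(dedup.subset(kept), gm_val, cohort_val, cfg)
```

Output on a 4,000-sample validation set simulated at OR/SD 1.55:

```
C+T: threshold 1.95e-07, 11 variants
EB: heterogeneity variance A = 5.38e-04 over 30 variants
combination alphas = [0.267 0.155], relative contributions = [0.63 0.37]
          PRS_CT: OR/SD 1.51 (1.41-1.61), AUC 0.607
          PRS_EB: OR/SD 1.49 (1.39-1.59), AUC 0.607
   PRS_CT+PRS_EB: OR/SD 1.51 (1.41-1.62), AUC 0.609
```

The C+T stage recovers 11 of the 12 planted causal signals' clumps; the
fitted OR per SD brackets the generating 1.55 (estimated PRSs are noisy
versions of the true score, so some attenuation is expected); the
combination improves discrimination only marginally because both components
track the same causal set.

The same machinery answers calibration questions directly. With control
distributions N(−0.328, 0.455²) (Indian) and N(−0.118, 0.439²) (Chinese),

```python
from transprs import calibration as cal
ind = cal.PopulationStats("Indian", -0.328, 0.455, 1018)
chi = cal.PopulationStats("Chinese", -0.118, 0.439, 6638)
cal.normal_percentile_map(ind, chi, 0.95)   # -> 0.890
```

an Indian woman at her own 95th percentile would be read as ~89th–90th
percentile against the Chinese distribution — a systematic risk
underestimate for every percentile.

A command-line interface wraps each stage (`transprs simulate|clump|
reweight|score|combine|evaluate|absrisk|calibrate|run`); `transprs run
--config cfg.txt --out rundir` executes the whole pipeline with a
reproducibility manifest (exit codes: 0 ok, 2 config, 3 data, 4 numerical).

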