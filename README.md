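# mrmediation

Two-sample Mendelian randomization (MR) with two-step mediation
analysis on GWAS summary statistics.

The motivating question is epidemiological: asthma is associated with a
reduced risk of colon cancer, and eosinophils — effector cells elevated
in asthma with known tumour-suppressive activity — are a plausible
intermediary. Given only per-SNP summary statistics (β, SE, p, alleles,
allele frequency) for three traits — an exposure *X* (asthma), a
candidate mediator *M* (eosinophil count) and an outcome *Y* (colon
cancer) — the package estimates how much of the causal effect of *X* on
*Y* runs through *M*.

## Model

Genetic variants serve as instruments. For SNP *j* with effects
β̂<sub>Xj</sub> on the exposure and β̂<sub>Yj</sub> on the outcome
(aligned to the same effect allele), the per-SNP Wald ratio is
β̂<sub>Yj</sub>/β̂<sub>Xj</sub>. The package implements:

* **Five univariable estimators** — inverse-variance weighted (IVW,
  weighted regression through the origin with weights 1/se²<sub>Yj</sub>),
  MR-Egger (free intercept; the intercept tests directional pleiotropy),
  weighted median, simple mode and weighted mode — plus Cochran's *Q*
  heterogeneity statistic. SEs use multiplicative random effects by
  default: the fixed-effect SE is inflated by max(1, √(Q/df)).
* **Multivariable MR (MVMR)** — weighted least squares of
  β̂<sub>Yj</sub> on (β̂<sub>X1j</sub> … β̂<sub>XKj</sub>) without
  intercept, giving each exposure's direct effect.
* **Two-step mediation** — β<sub>xz</sub> (exposure→mediator, UVMR) and
  β<sub>zy′</sub> (mediator→outcome adjusted for the exposure, MVMR)
  give the indirect effect

  β<sub>mediating</sub> = β<sub>xz</sub> · β<sub>zy′</sub>,

  with SE by the first-order delta method
  √(β²<sub>xz</sub>se²<sub>zy′</sub> + β²<sub>zy′</sub>se²<sub>xz</sub>)
  and by parametric bootstrap, and the proportion mediated
  β<sub>mediating</sub>/β<sub>total</sub> with a percentile bootstrap CI.
* **Instrument selection** (p < 5×10⁻⁸, greedy clumping at ≥10,000 kb /
  r² < 0.001, confounder exclusion lists) and **allele harmonization**
  (swaps, strand flips, frequency-based resolution of palindromic SNPs).
* **A seeded simulator** generating three-study summary statistics under
  the causal graph X → M → Y with a direct X → Y path, configurable
  pleiotropy, and allele/strand scrambling — so every stage is testable
  against known ground truth without downloading GWAS data.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data. `analysis/01_simulate_studies.py` generates three studies of 300
SNPs under the paper-like scenario (total effect ln 0.830, 51.7% of it
mediated); `analysis/02_univariable_mr.py` then prints:

```
method               OR          95% CI         p  J
ivw               0.831 (0.819, 0.843) 1.19e-135  109
egger             0.813 (0.785, 0.843)  4.94e-20  109
weighted_median   0.826 (0.808, 0.844)  8.92e-68  109
simple_mode       0.825 (0.787, 0.865)     2e-15  109
weighted_mode     0.819 (0.791, 0.847)  1.87e-30  109
Cochran Q = 117.2 (df 108, p = 0.257)
Egger intercept = 0.0012 (p = 0.195)
```

109 of 150 exposure instruments survive genome-wide selection; all five
estimators agree on a protective odds ratio near the generative 0.830,
with no heterogeneity or pleiotropy signal. `analysis/03_mediation.py`
completes the decomposition:

```
total effect       -0.1849 (se 0.0075)   [truth -0.1863]
beta_xz             0.3122 (se 0.0082)   [truth 0.3100]
beta_zy'           -0.3054 (se 0.0047)   [truth -0.3108]
indirect effect    -0.0953 (delta se 0.0029, bootstrap se 0.0030)
proportion mediated 51.5% (95% CI 46.7% to 57.1%)   [truth 51.7%]
```

i.e. roughly half of the protective effect of the exposure on the
outcome is carried by the mediator, and the delta-method and bootstrap
SEs of the indirect effect agree. `analysis/04_calibration_study.py`
repeats this over 200 seeded replicates (mean IVW bias 0.0009, 96%
empirical CI coverage, Egger intercept 0.0200 under generative
directional pleiotropy of 0.02).

The same stages are available as a CLI:

```sh
mrmediation simulate --scenario paper-like --seed 1 --out sim/
mrmediation mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv --seed 1 --out run/
mrmediation mediate --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
    --outcome sim/outcome.tsv --seed 1 --out run/
mrmediation check-consistency 0.830 0.717 0.962
```

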