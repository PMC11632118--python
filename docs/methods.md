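# Methods

## Setting and model

The package works entirely on GWAS summary statistics: for each SNP
*j* and each trait, a per-allele effect estimate β̂ⱼ, its standard
error, the effect and other alleles, the effect-allele frequency, a
p-value and a sample size. Three traits form a mediation triangle — an
exposure *X*, a mediator *M*, an outcome *Y* — with structural effects
*a* (X→M), *b* (M→Y given X) and *c′* (X→Y given M). The total effect
of the exposure is c′ + a·b, the indirect (mediated) effect a·b, and
the proportion mediated a·b/(c′ + a·b). Binary-trait effects (exposure
and outcome here) are interpreted on the log-odds scale, so exp of an
estimate is an odds ratio.

Instrumental-variable assumptions: each instrument is associated with
its trait (relevance, enforced by the p < 5×10⁻⁸ screen), independent
of confounders, and affects the outcome only through the modelled
exposures (no horizontal pleiotropy — probed, not guaranteed, by the
Egger intercept and Cochran's Q).

## Instrument selection

Three criteria, in order: (1) genome-wide significance with a strict
inequality, p < 5×10⁻⁸; (2) approximate independence by greedy
clumping — SNPs are ranked by ascending p-value (ties broken by rsid so
the result is independent of row order), each surviving SNP removes all
SNPs on the same chromosome closer than 10,000 kb or with known
pairwise r² ≥ 0.001; (3) removal of rsids on a user-supplied
confounder-association list, because confounder screening is performed
against external GWASs and cannot be derived from the three input
studies. An r² missing from the LD table is only binding within the
distance window, where the pair is discarded anyway; across windows an
absent r² is treated as no evidence of dependence.

## Harmonization

All betas are re-expressed relative to the exposure study's effect
allele. Non-palindromic SNPs are resolved textually: allele swap
(negate beta, complement frequency), strand flip (relabel only), or
both; irreconcilable allele sets and duplicated/multi-allelic rsids are
dropped with a per-reason tally, never raised. Palindromic SNPs (A/T,
G/C) cannot be resolved textually; the strand is inferred from
effect-allele-frequency concordance when both frequencies are present
and outside the ambiguity window [0.42, 0.58]: concordant within a
tolerance of 0.08 keeps the textual alignment, concordant only with the
complement flips it, anything else drops the SNP as
`palindromic-ambiguous`. The window and tolerance are configurable;
the defaults mirror the de facto standard in two-sample MR software.
Harmonization is idempotent, and estimators are invariant to jointly
negating any SNP's aligned betas.

MR-Egger additionally requires every exposure beta to be non-negative;
`orient_positive_exposure` negates the full beta vector of offending
SNPs (a relabelling of the effect allele). Ratio-based estimators are
unaffected by this; the Egger intercept is defined relative to the
exposure-raising allele.

## Estimators

With aligned (β̂ₓⱼ, β̂ᵧⱼ, seᵧⱼ) and Wald ratios rⱼ = β̂ᵧⱼ/β̂ₓⱼ with
first-order SEs seᵧⱼ/|β̂ₓⱼ|:

* **IVW**: b̂ = Σβ̂ₓⱼβ̂ᵧⱼseᵧⱼ⁻² / Σβ̂ₓⱼ²seᵧⱼ⁻², the weighted
  through-origin regression, algebraically identical to the
  inverse-variance-weighted mean of the rⱼ under first-order ratio SEs
  (asserted in tests to 10⁻¹⁰ relative). Fixed SE (Σβ̂ₓⱼ²seᵧⱼ⁻²)^(−1/2);
  the default multiplicative-random-effects SE multiplies it by
  max(1, √(Q/(J−1))), so heterogeneity can only widen intervals.
  p-values from the normal distribution.
* **MR-Egger**: weighted regression with free intercept; slope = causal
  estimate, intercept = average directional pleiotropic effect. Both
  p-values from t(J−2), both SEs inflated by max(1, √(Q_egger/(J−2))).
* **Weighted median**: sort ratios, normalize weights wⱼ (inverse ratio
  variances; equal weights give the simple median), interpolate
  adjacent ratios where the centred cumulative weight Sⱼ − wⱼ/2 crosses
  ½. SE by parametric bootstrap: each ratio redrawn from
  Normal(rⱼ, se²ⱼ), n_boot = 1000 by default, seed mandatory.
* **Simple/weighted mode**: normal-kernel density of the ratios with
  bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) (φ = 1 by default),
  evaluated on 512 points spanning [min−3h, max+3h]; the estimate is
  the grid argmax (ties toward the smaller value); identical ratios
  (h = 0) return the common ratio. Bootstrap SE as for the median.
* **Cochran's Q**: Σwⱼ(rⱼ − b̂)² with wⱼ the inverse ratio variances,
  df = J−1, upper-tail χ² p-value.

First-order (not second-order) Wald-ratio SEs are used throughout,
matching common practice; the neglected β̂ᵧ²se²ₓ/β̂ₓ⁴ term is second
order in 1/F and negligible for the strong instruments these analyses
assume.

**MVMR** solves the weighted normal equations of β̂ᵧⱼ on the K exposure
beta columns (weights seᵧⱼ⁻², no intercept), requires J > K, reports
per-exposure SEs from (XᵀWX)⁻¹ inflated by max(1, √(Q/(J−K))), and logs
the weighted design's condition number (ratio of extreme singular
values) as a soft diagnostic; condition numbers above 10⁸ raise a
degenerate-design error. A column of exactly zero instrument effects is
excluded from the solve (its exposure gets a NaN effect), which makes
the model reduce exactly to univariable IVW for the remaining exposure —
the behaviour the reduction property requires — while genuinely
collinear designs (e.g. duplicated columns) still error. The MVMR
instrument set is the union of the per-exposure selections, re-clumped
jointly, complete-case across all studies.

## Mediation

β_total is the univariable IVW estimate (configurable), β_xz the UVMR
exposure→mediator estimate, β_zy′ the mediator's direct effect from
MVMR of {exposure, mediator} on the outcome. The indirect effect is the
exact product β_xz·β_zy′; its delta-method SE is
√(β²_xz se²_zy′ + β²_zy′ se²_xz), with the exact-variant flag adding
the (non-negative) se²_xz se²_zy′ term. The bootstrap SE and CI draw
the two coefficients independently from their sampling normals
(n_boot = 5000 default, n_boot ≥ 100 enforced, seed mandatory) — the
two-step design fits them in separate regressions, and their
independence is an assumption recorded in the result object.
SNP-level resampling is deliberately not the default: the method
operates on summary coefficients. The proportion mediated is the exact
ratio β_mediating/β_total, with a percentile CI from paired draws
(total drawn from its own normal); percentile rather than BCa because
the sampling distributions here are near-normal and percentile is the
simplest defensible choice. Opposite signs of indirect and total
effects set an `inconsistent-mediation` flag, |proportion| > 1 a
`proportion-gt-1` flag.

One identity worth stating precisely: multiplying *all* betas by a
constant does not preserve the proportion (the product scales
quadratically, the total linearly); what the proportion is invariant
to is rescaling the mediator's units — β_xz → kβ_xz together with
β_zy′ → β_zy′/k — and that is the invariance the tests assert.

## Synthetic data generator

The generator emulates the study conditions directly at the
summary-statistic level; no individual-level genotypes are drawn.
Defaults (chosen once, as the conditions of the simulation study):

* J = 150 exposure instruments, J_m = 150 mediator-specific
  instruments; per-study sample sizes n_x = 360,000, n_m = 170,000,
  n_y = 200,000 — the scale of the biobank asthma, blood-cell-trait and
  cancer GWASs the setting mimics.
* Paper-like structural effects a = 0.31, b = −0.3108, c′ = −0.09, so
  the total is ln(0.830) to three decimals and the true mediated
  proportion 0.517.
* MAFs uniform on (0.05, 0.45); instrument effects γⱼ ~ Normal(0, σ²)
  with σ calibrated so the mean instrument F at the exposure study is
  300 (strong instruments; SNPs whose realized effect is too weak are
  removed by the p < 5×10⁻⁸ screen, leaving ~110 of 150). The
  weak-instruments scenario sets mean F = 15.
* Observed betas add independent Normal(0, seⱼ²) noise per study with
  seⱼ = 1/√(2·maf(1−maf)·n) — the standard large-sample SE of a
  per-allele regression coefficient on a standardized trait —
  independence across studies matching the two-sample design.
  p-values are computed exactly from the observed z.
* Pleiotropic direct effects δⱼ (none / balanced zero-mean /
  directional with configurable mean and sd) are specified relative to
  the exposure-raising allele, the orientation in which Egger regression
  analyses instruments; on the raw allele they carry the sign of γⱼ.
* 10% of SNPs are palindromic and 10% of non-palindromic SNPs are
  reported on the opposite strand in the mediator/outcome studies;
  half of all SNPs are reported with swapped alleles; allele
  frequencies get Normal(0, 0.005) observation noise. This exercises
  every harmonization path on every run.
* Instruments are placed >10 Mb apart across chromosomes 1–22 and are
  mutually independent — the regime real instruments are in *after*
  clumping, consistent with the r² < 0.001 criterion.

What the generator does **not** model: LD between instruments, sample
overlap between studies, winner's-curse selection in the discovery
GWAS, liability-threshold effects for the binary traits, population
stratification. Passing recovery tests therefore demonstrates
correctness of the estimators and plumbing under the stated model, not
robustness to those real-data complications.

## Numerical choices and degenerate inputs

Records with se ≤ 0 or identical alleles are rejected at the boundary;
a p-value disagreeing with 2Φ(−|β/se|) by more than a factor of two is
flagged, not dropped (published stats are rounded). SNPs with zero
exposure beta are excluded from ratio-based estimators with a logged
reason. Estimator minimums: 2 SNPs (IVW, Q), 3 (Egger, median, modes);
below them an insufficient-instruments error is raised rather than a
silent result. The 95% interval multiplier is 1.959964 everywhere, and
OR-scale values are exact exponentials of the log-scale values.

## Problem sizes

The replicate studies use 200 seeded replicates at J = 150 + 150 and
the sample sizes above; the calibration driver and the acceptance
script complete in about a minute on one core. Bootstrap defaults are
1000 draws (estimator SEs) and 5000 (mediation), reduced to 100–500 in
replicate loops where only point estimates are consumed.
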