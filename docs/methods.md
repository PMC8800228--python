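# Methods

## Model and assumptions

The package operates entirely in the two-sample summary-statistics MR
setting: genetic variants G₁…G_J serve as instruments for an exposure X
(here a quantitative trait in SD units), and the causal effect θ of X on a
binary outcome Y (log-odds scale) is estimated from published per-variant
association coefficients. The usual instrumental-variable assumptions are
taken as given for the *valid* instruments — association with X,
independence from confounders, and no effect on Y except through X — and
the toolbox exists precisely to probe the third assumption (pleiotropy) and
a fourth, usually implicit one: that the outcome dataset actually measures
the outcome. Proxy-phenotype (GWAX) datasets, where "case" means a
self-reported parental history, can violate that silently; the
heterogeneity layer quantifies the resulting divergence.

Per variant, θ̂_j = β̂_Yj/β̂_Xj with first-order variance
v_j = se(β̂_Yj)²/β̂_Xj². The exposure-side sampling error is ignored in v_j
(the standard NOME approximation); with instruments conditioned on
genome-wide significance the neglected term θ²se_Xj²/β̂_Xj² is two orders
of magnitude below se_Yj²/β̂_Xj² at the default settings.

## Estimators

**IVW.** β̂ = Σw_jθ̂_j/Σw_j, w_j = 1/v_j. The fixed-effect SE is
(Σw_j)^{−1/2}; the multiplicative random-effects SE multiplies it by
max(1, √(Q/(J−1))) where Q = Σw_j(θ̂_j−β̂)². The default `auto` model uses
the fixed SE for J < 4 and multiplicative random effects otherwise; the
point estimate is model-invariant, so odds ratios are unaffected. p-values
use the normal reference.

**Weighted median.** Order θ̂_(1)…θ̂_(J); with standardized cumulative
weights p_j = (S_j − w_j/2)/S_J the estimate interpolates linearly at
p = 1/2. The SE is a parametric bootstrap: θ̂*_j ~ N(θ̂_j, v_j), recompute
the weighted median, take the SD over n_boot replicates (default 10,000;
the seed is a required argument so results are reproducible).

**MR-Egger.** Variants are first oriented so β̂_Xj ≥ 0 (both coefficients
negated otherwise) — without a fixed orientation the intercept is not
identified. β̂_Y is regressed on β̂_X with intercept and weights 1/se_Yj²;
the slope estimates θ under the InSIDE assumption and the intercept the
average directional pleiotropy. SEs carry the multiplicative
overdispersion factor max(1, σ̂) (σ̂ = residual SE of the weighted fit),
and both tests use the t reference with J−2 df. 95% CIs elsewhere use
z = 1.959964.

**MR-PRESSO.** The observed statistic is
RSS = Σ_j w_j (β̂_Yj − θ̂_(−j)β̂_Xj)² with leave-one-out IVW slopes
θ̂_(−j) and w_j = 1/se_Yj². The null is simulated parametrically:
β̂*_Xj ~ N(β̂_Xj, se_Xj²), β̂*_Yj ~ N(θ̂_(−j)β̂_Xj, se_Yj²), with the
leave-one-out slopes re-estimated inside each replicate. Global p is the
add-one empirical tail (1 + #{RSS* ≥ RSS})/(n_sim + 1), so p ≥ 1/(n_sim+1)
by construction. The outlier test compares each variant's observed
weighted squared residual to its own simulated distribution and
Bonferroni-multiplies the empirical p by J; flagged variants are removed
in a single pass and IVW on the remainder is the corrected estimate.
Note the resolution limit: no variant can be flagged unless
n_sim·α > J (a warning is logged), so J ≈ 150 panels need the default
n_sim = 10,000. Draws come from per-variant substreams keyed by
(seed, crc32(rsid)), which makes results order-invariant — a deliberate
departure from the original order-dependent RNG sequence; equivalence with
that implementation is distributional, not bitwise. The distortion test is
not implemented.

## Cross-dataset heterogeneity

For one variant observed in outcome datasets A and B, Cochran's Q with
inverse-variance weights and k = 2 reduces to
Q = (θ̂_A − θ̂_B)²/(v_A + v_B), referred to χ²₁, and
I² = max(0, (Q−1)/Q)·100% is banded low [0,25), moderate [25,50),
large [50,75), extreme [75,100]. Band counts use strict ">" so boundary
values fall in the lower band. No multiplicity correction is applied to the
per-variant Q p-values — the reported summaries are I² band counts. The
systematic component of the divergence is tested by a paired-samples t-test
on the aligned Wald estimator vectors (sample SD, n−1 df); identical
vectors raise a degenerate-variance error rather than returning p = NaN.
Q and the t-test both assume the two datasets are independent samples,
which is why comparisons are restricted to dataset pairs that do not share
participants (clinical GWAS vs proxy-only GWAX), and why no ANOVA across
overlapping meta-analytic datasets is offered.

## Harmonization choices

Matching is by rsID and alleles. Non-palindromic pairs resolve by direct
match, swap (β_Y negated), strand complement, or complement+swap;
irreconcilable allele sets are dropped as data, with reasons, never as
exceptions. Palindromic variants follow a policy: `drop`, `keep` (trust
same-strand reporting; kept but marked ambiguous), or the default
`eaf_infer`, which aligns by letters, then compares which side of 0.5 the
two effect-allele frequencies fall on; either frequency missing or inside
0.5 ± 0.08 (window configurable) drops the variant as
"palindromic-ambiguous". Exposure effects with |β̂_X| < 1e−12 are dropped
("weak-zero") because the Wald variance divides by β̂_X². Harmonizing an
already-harmonized pair is a no-op (idempotence is tested), and the Wald
ratio is invariant to which allele is called "effect" (both coefficients
flip).

## Pipeline

Per outcome dataset: harmonize → MR-Egger intercept screen and MR-PRESSO
global + outlier tests on the full panel → exclude flagged variants →
IVW, weighted median, MR-Egger, PRESSO-corrected estimates. The secondary
analysis intersects the harmonized variant sets of all outcome datasets,
removes the union of all flagged pleiotropic variants, and reruns the four
estimators per dataset on that common panel; heterogeneity and paired-t
comparisons run on the same shared panel. Exclusion is driven by the
PRESSO outlier test only; the Egger intercept is reported as a screen but
does not remove variants. The significance threshold is 0.05 throughout,
without cross-dataset or cross-method multiplicity correction. The report
is a pure function of (inputs, config, seed); sub-seeds for the bootstrap
and the PRESSO simulations are derived from the master seed and the
dataset label.

## Synthetic generator

`simulate_study` draws, per variant: γ_j ~ N(0, gamma_sd²) (redrawn until
the realized exposure statistic reaches `select_p_threshold`, default
5e−8 — the generator emulates a *published* instrument list, every member
of which passed genome-wide significance in its source GWAS);
β̂_Xj = γ_j + N(0, se_Xj²); and per dataset d
β̂_Y,d,j = λ_d θ_d γ_j + α_j sign(γ_j) + b_{d,j} + N(0, se_y,d,j²),
with pleiotropy α_j ~ N(pleiotropy_mean, pleiotropy_sd²) on a configured
fraction of variants, dilution λ_d a multiplicative slope factor,
b_{d,j} ~ N(0, tau²) per-variant between-dataset heterogeneity, and SEs
drawn uniformly from configured ranges. Pleiotropy is applied per
exposure-increasing allele (hence the sign(γ_j) factor): that is the
orientation in which the Egger intercept is defined, and it makes
`pleiotropy_mean` the estimand of the intercept; adding α_j in the
reported-allele orientation would cancel across symmetric instrument signs
and estimate zero. `noise_scale` multiplies all sampling noise so the
zero-noise limit leaves the structural model exact while reported SEs stay
positive (used by exactness tests). All draws flow through substreams
named by purpose (and rsID where relevant), so components are independently
reproducible; `inject_outlier` shifts one outcome beta by a chosen number
of its SEs, on the harmonized orientation, and records the fact in the
ground truth.

Defaults are the study conditions of the motivating analysis: J = 143
shared instruments, gamma_sd = 0.025 and se_X ∈ [0.0025, 0.0045]
(typical of lead variants from a ~400k-sample GWAS of a quantitative
trait), se_Y ∈ [0.015, 0.035] (typical log-odds SEs for AD-scale
case–control data), and per-dataset slopes θ = −0.34 (clinical GWAS),
+0.13 (2018 proxy), +0.65 (2021 proxy) — the average Wald estimators the
divergence analysis is designed to expose. tau, pleiotropy and dilution
default to 0/off; tau is in outcome log-odds units, so per-variant
heterogeneity becomes visible when tau is of the order of se_Y.

What the generator does *not* emulate: LD between instruments (instruments
are independent by design), allele-frequency-dependent SEs, sample overlap
between datasets, winner's-curse beyond the significance conditioning, and
liability-threshold misclassification (dilution is a slope factor plus
independent noise, not a structural misclassification model). Tests that
pass on this generator therefore validate the estimators and their
calibration under clean two-sample assumptions, not robustness to overlap
or LD.

## Numerical and degenerate-input conventions

Empirical p-values use the add-one estimator (never 0). Exactly collinear
Egger inputs give σ̂ = 0; SEs then degenerate to 0 and the CI collapses to
the point estimate rather than dividing by zero. Weighted-median
interpolation clamps to the extreme order statistics when p = 1/2 falls
outside [p₁, p_J]. Duplicate rsIDs are a hard error on read (an ambiguous
instrument cannot be silently resolved); invalid rows are rejected
individually with reasons and surface in a validation report. Summary
tables round-trip exactly (floats parsed with round-trip precision).

## Known limitations

- PRESSO global p-values from other implementations are matched only in
  distribution, not value-for-value, because the simulated null depends on
  the RNG stream.
- The weighted-median bootstrap SE is itself Monte-Carlo noisy at small
  n_boot; the default 10,000 keeps the SE's own error near 1%.
- IVW coverage under the default generator runs a fraction of a percent
  below nominal (~94–95% empirically): significance conditioning induces a
  small winner's-curse attenuation of the ratio estimates. It is visible
  in the acceptance calibration output rather than hidden by recalibration.
- The reproduction of the published per-variant analysis requires the
  original supplementary tables (see README); they ship with neither this
  package nor its tests.

## Problem sizes

The test suite and acceptance script size their simulations to keep the
whole run in seconds on one core: calibration loops use J = 20–50 variants
with n_sim = 500–1,000 and 200–1,000 replicates; single-study analyses use
the full default J = 143 with n_sim up to 10,000. These sizes hold every
Monte-Carlo tolerance asserted in the tests with comfortable binomial
margins.
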