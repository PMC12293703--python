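# Methods

## The design

Two-sample Mendelian randomization treats genetic variants as instrumental
variables: if a variant is robustly associated with an exposure, independent
of confounders, and affects the outcome only through the exposure, the ratio
of its outcome and exposure associations estimates the causal effect. The
*network* extension runs three such analyses — exposure→outcome (the total
effect), exposure→mediator, and mediator→outcome — and attributes the share
(β_xm·β_my)/β_total of the total effect to the mediated path. All estimation
operates on per-variant summary statistics (β, SE, allele pair, effect-allele
frequency, p, n) from separate, non-overlapping GWAS panels; the package
never touches individual-level data.

## Instruments

Variants pass a genome-wide significance screen (default p < 5×10⁻⁸) and are
pruned to mutual independence by greedy p-ranked clumping: accept the most
significant remaining candidate, discard everything with r² above the
threshold (default 0.001) against any accepted variant, repeat. The r² values
come from a user-supplied sparse pair table; the package does not compute LD
from reference panels. Strength is summarized per SNP as R² = 2p(1−p)β² — the
variance explained on a trait standardized to unit variance — and
F = (n−2)·R²/(1−R²); at the score level, F = ((n−k−1)/k)·R²/(1−R²) on the sum
of per-SNP R² (additive under post-clumping independence). For binary
exposures these are log-odds-scale approximations and should be read as
indicative. Instruments with F < 10 are flagged by the conventional
weak-instrument rule. With the published SHBG inputs (k = 241, R² = 12.0%,
n = 312,215) the GRS formula gives F ≈ 176.5, i.e. 177 at printed precision,
which is what fixed the R²/F convention above.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele. Exact
allele matches pass through; swapped alleles negate β and complement the
frequency; complementary-strand reports are complemented first. Palindromic
pairs (A/T, C/G) are strand-ambiguous from alleles alone: when both
frequencies are available and both fall outside 0.5 ± `palindrome_window`
(default 0.08, the conventional 0.42–0.58 exclusion band; configurable
because published practice varies), the orientation that makes the
minor-allele designation agree is taken, otherwise the variant is dropped.
Variants missing the effect-allele frequency can never be palindromically
resolved and are dropped in that branch only. Instruments absent from the
outcome panel may be replaced by the best available proxy with r² ≥ 0.8 (ties
broken by id for determinism), keeping the instrument's exposure statistics.
Because the LD table carries r² without sign, proxy orientation is decided by
frequency matching against the instrument's exposure EAF — a good
approximation at r² ≥ 0.8, where allele frequencies nearly coincide, but an
approximation nonetheless; proxies without usable frequencies are skipped. A
per-variant audit (status and reason, statuses summing to the candidate
count) accompanies every harmonized set.

## Estimators

Fixed-effect IVW is the inverse-variance-weighted mean of the per-SNP Wald
ratios with weights β²ₓ/se²ᵧ, algebraically identical to weighted least
squares of βᵧ on βₓ through the origin, and — as documented in the code —
numerically identical to the summary-statistics GRS estimator, retained as a
named method for report parity. The first-order delta method gives the Wald
SE (se_y/|βₓ|); second-order terms are ignored, which is standard at F ≫ 10.
Heterogeneity is Cochran's Q of the ratios about the IVW estimate
(df = k−1), with I² = max(0, (Q−df)/Q)·100. The multiplicative
random-effects variant keeps the IVW point estimate and inflates the SE by
√max(1, Q/(k−1)); the floor at 1 means homogeneous sets are never rewarded
with shrunken uncertainty (some implementations allow φ < 1; this one
deliberately does not). MR-Egger fits a weighted regression *with* intercept
after re-orienting all exposure effects non-negative; dispersion is estimated
from the weighted residuals, and both coefficients are tested against t with
k−2 degrees of freedom. IVW p-values use the normal reference distribution.
Confidence intervals are β ± 1.96·SE throughout; binary-outcome estimates
live on the log-OR scale and are exponentiated only at reporting time.

## Sensitivity battery and reporting rule

MR-PRESSO computes, for each SNP, the leave-one-out IVW slope and the
residual βᵧⱼ − β̂₍₋ⱼ₎βₓⱼ; the observed (unweighted) residual sum of squares is
compared against parametric-bootstrap replicates drawn as
β*ₓ ~ N(βₓ, se²ₓ), β*ᵧ ~ N(β̂₍₋ⱼ₎βₓ, se²ᵧ) with the leave-one-out slopes
recomputed inside each replicate. Empirical p-values use +1 smoothing (never
exactly zero; floor 1/(n_sim+1)). Per-SNP outlier p-values are
Bonferroni-corrected across k, so the detection floor is k/(n_sim+1); calls
with that floor at or above α emit a warning, and the pipeline driver raises
n_sim to ⌈k/α⌉+1 when needed. The distortion test compares the
outlier-removed minus full-set slope difference against 1000 random removals
of the same count. The bootstrap is approximately calibrated: measured global
type-I error ≈ 5.2% at k = 100 and ≈ 6.8% at k = 20 (the small-k inflation
reflects ignored slope-estimation uncertainty and is inherited from the
method's design). In the pipeline, outlier removal iterates (max 5 rounds)
until the global test is non-significant — this stands in for external
pleiotropy-catalog screening, which is out of scope; an explicit exclusion
list can be supplied instead. The reporting rule follows the heterogeneity
verdict strictly: fixed-effect IVW iff Q's p > 0.05 *and* I² < 25%, otherwise
the multiplicative-random-effects SE; the Egger-intercept verdict
(directional pleiotropy iff p ≤ 0.05) is always attached. Leave-one-out
re-estimation flags any variant whose exclusion changes the estimate's sign
or the CI's exclusion of zero.

## Network orchestration

Each leg runs selection → clumping → harmonization → iterative PRESSO →
estimation → diagnostics, with errors labelled by leg. Mediators are screened
one at a time (marginally): a candidate qualifies when the exposure→mediator
effect reaches p < 0.05 in the discovery panel *and* in an independent
replication panel with concordant direction. Qualified mediators are
instrumented by their own genome-wide-significant variants for the
mediator→outcome leg, and the forward mediated proportion combines the three
legs by the product-of-coefficients ratio, with odds ratios entered as ln OR
— the convention that exactly reproduces the published worked examples
(18.9% and 22.8%) from their printed inputs, and is therefore taken as the
intended formula. Its SE comes from the first-order delta method treating
the three estimates as independent (they derive from distinct samples):

var ≈ (β_my/β_t)²se²_xm + (β_xm/β_t)²se²_my + (β_xm·β_my/β_t²)²se²_t.

A seeded parametric bootstrap (10,000 draws) is available as a cross-check;
the two agree closely whenever |β_total| ≫ se_total, and the bootstrap is
preferable near that boundary where the ratio's distribution is heavy-tailed.
Proportions outside [−1, 1] (inconsistent mediation) are reported with a
warning rather than suppressed. No multiple-testing correction is applied
across mediators or outcomes by default (screening is at raw p < 0.05); a
Bonferroni switch exists. The reverse direction re-runs the design with
mediator and exposure roles swapped; forward and reverse analyses therefore
use disjoint instrument sets up to the small overlap the report records
(see below). The step-3 estimate is univariable — no adjustment for the
exposure — consistent with the printed arithmetic it reproduces.

## Synthetic data

The generator emulates consortium-style two-sample panels. Exposure
instruments get true effects b_x ~ N(0, scale²) rejection-sampled until
genome-wide significant at the exposure n; because selection acts on the
truth and observed effects are then drawn as truth + N(0, se) independently
per panel, instruments are free of winner's curse, as in a clean two-sample
design. The mediator's value is γ_xm · (exposure genetics) plus
mediator-specific instruments with their own truncated effects — without
these the mediator→outcome leg would be unidentified (every
mediator-associated SNP would act through the exposure, and its ratio would
estimate total/γ rather than θ_my) and the forward/reverse instrument sets
could not be disjoint. The outcome is θ_direct·b_x + θ_my·b_m plus an
optional pleiotropy term expressed per exposure-increasing allele (so a
directional mean shifts the Egger intercept rather than cancelling across
arbitrary allele orientations). Standard errors follow
se = 1/√(2p(1−p)n) for quantitative panels and
se = √(1/(n·prev(1−prev)) · 1/(2p(1−p))) for binary outcomes at configurable
prevalence (default 0.1) — a log-OR approximation that avoids
individual-level simulation. Planted outliers multiply the outcome truth by
10 for a chosen fraction of SNPs. Optional LD is block-structured (disjoint
cliques of uniform r²), sufficient to exercise clumping but not a model of
real LD decay. Allele codes are drawn from non-palindromic pairs, and the
non-exposure panels randomly scramble orientation and strand so that
harmonization is exercised on every run.

Defaults — k = 100 instruments per trait, n = 100,000 per panel,
MAF ~ U(0.05, 0.5), effect scales 0.03 (exposure) and 0.05 (mediator),
γ_xm = −0.3, θ_my = 0.4, θ_direct = −0.05 — put per-SNP F statistics in the
~30–3000 range typical of strong published instruments and give a mediated
proportion of 0.12/0.17 ≈ 0.706. What passing tests on these data do *not*
show: robustness to realistic LD structure, sample overlap, winner's curse
from observed-p selection in the exposure panel of real single-sample
designs, population stratification, or allele-frequency mismatch between
panels — none of which the generator models.

## Numerical and degenerate-input choices

Empirical p-values are +1-smoothed; analytic p-values are clipped into
(0, 1]. A single harmonized SNP falls back to the Wald ratio with a logged
note; Egger and leave-one-out require k ≥ 3, PRESSO k ≥ 4. Zero exposure
betas, zero-variance Egger designs, zero retained harmonized records, and a
zero total effect in the mediation ratio raise typed errors rather than
returning NaN. Proxy ties break lexicographically; clumping is deterministic
given the input order. All Monte-Carlo components take explicit seeds; the
pipeline derives per-leg seeds from the run seed and the leg label so legs
are reproducible independently.

## Known limitations

Egger's intercept test runs slightly hot (≈8–9% at α = 0.05) under the
default generator because exposure-side measurement error perturbs the
regression — a known property of MR-Egger when the no-measurement-error
assumption is violated, visible here precisely because the generator draws
observed exposure effects with noise. The mediator-instrument screen can
admit a few exposure-chain SNPs whose mediator association is strong by
chance (the run report records the overlap); their ratios estimate total/γ
rather than θ_my and contribute a small attenuation-like bias to step 3 at
the default effect scales. Mediation CIs are first-order delta-method
intervals; for proportions near 0 or 1, or totals near zero, prefer the
bootstrap. R²/F reporting for binary exposures is approximate. The package
deliberately implements no weighted-median/mode estimators, no multivariable
MR, no Steiger filtering, and no graphical output beyond plain tables.
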