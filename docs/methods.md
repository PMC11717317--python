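# Methods

## Model and estimators

Two-sample MR treats the per-variant summary associations of an exposure X
and an outcome Y, estimated in non-overlapping samples, as the data. For
variant *j* with exposure effect β̂_Xj (SE s_Xj) and outcome effect β̂_Yj
(SE s_Yj), the Wald ratio θ̂_j = β̂_Yj / β̂_Xj estimates the causal slope θ
if the variant is a valid instrument. Its SE uses the first-order delta
approximation s_Yj / |β̂_Xj|, which ignores the exposure-side noise; this is
the dominant convention and is accurate for strong instruments (the ignored
term is O(θ²s_Xj²/β_Xj²), about 1% of the variance at F ≈ 300).

**IVW.** θ̂ = Σw_jθ̂_j / Σw_j with w_j = 1/se(θ̂_j)². The fixed-effect SE is
(Σw_j)^{−1/2}; the multiplicative-random-effects (mre) SE multiplies it by
max(1, √(Q/(L−1))) with Q = Σw_j(θ̂_j − θ̂)², so mre is never
anti-conservative relative to fe and the point estimate is identical under
both. IVW is algebraically the weighted least-squares fit of β̂_Y on β̂_X
through the origin with weights 1/s_Yj² — a dual route used as an
independent test oracle.

**MR-Egger.** WLS of β̂_Y on β̂_X with a free intercept, weights 1/s_Yj²,
after orienting every record so β̂_X ≥ 0. The intercept estimates the mean
directional pleiotropic effect; the slope is consistent for θ under the
InSIDE assumption. Both SEs carry the floored overdispersion scale
max(1, √(RSS_w/(L−2))) and p-values use t(L−2). The floor also makes
exact-fit data (RSS = 0) degenerate gracefully to the unscaled
(X'WX)^{−1} covariance rather than dividing by zero.

**Weighted median.** Ratios are ordered, weights normalized, and the
estimate interpolates θ̂_(j) against the cumulative weight midpoints
p_j = Σ_{i≤j}w'_i − w'_j/2 at 0.5; with equal weights and odd L this is the
plain median. The SE is the SD of the estimate over parametric-bootstrap
replicates (default 1,000) resampling each θ̂_j from Normal(θ̂_j, se_j)
with weights held fixed. This bootstrap is mildly conservative for
median-type statistics because the resampling centers are themselves noisy;
its coverage in our calibration runs sits near 97% rather than 95%
(see Limitations).

**Modes.** The (simple/weighted) mode is the argmax of a normal-kernel
density of the ratios on a 512-point grid, bandwidth = bandwidth_factor ×
0.9·min(sd, MAD_normal)·L^{−1/5} (modified Silverman rule; if one of
sd/MAD is zero the other is used, and an exact point mass returns the
common value directly). Weighted variant weights each point by 1/se_j².
Bootstrap SE as for the median.

**Decision rules.** Heterogeneity: Cochran's Q against χ²(L−1); Q p < 0.05
selects ivw_mre as the primary model, otherwise ivw_fe (strict inequality,
so p = 0.05 selects fe). Pleiotropy: Egger intercept p < 0.05. Robustness:
a result is labelled robust iff at least one of IVW, MR-Egger, weighted
median is significant at the (raw) α and all three slopes share one sign;
the Bonferroni-adjusted threshold α/m is reported alongside rather than
substituted, since which family the correction spans is a study-level
choice (m defaults to the number of outcomes and is recorded in the run
manifest). All thresholds are config-exposed with 0.05 defaults.
Leave-one-out re-runs IVW with the same effects model as the primary
analysis, for internal consistency.

**MVMR.** Joint WLS of β̂_Y on the K-column exposure-beta matrix, no
intercept, weights 1/s_Yj², floored overdispersion scale
max(1, √(RSS_w/(L−K))), t(L−K) p-values. The instrument set is the union of
per-exposure instruments restricted to variants present in every dataset
("union-then-available"): a pure intersection of instrument sets across
unrelated traits is typically empty, which would make any adjustment
analysis impossible; the intersection rule remains selectable. A co-exposure
whose betas are identically zero is dropped from the design matrix with a
zero coefficient so the fit degenerates to the lower-dimensional model;
any other rank deficiency is a hard error naming the collinear exposures.
When a pairwise-r² source is supplied, the pooled candidate set is jointly
clumped (same r²/window thresholds) before estimation; without one, the
step is skipped — the library consumes precomputed r² tables and never
touches genotype panels. The default adjustment design is one co-exposure
at a time (K = 2), matching how confounder adjustments are usually
reported; an all-at-once mode is just a longer exposure list.

## Instrument selection

Filters run in the order significance → MAF → weak-instrument F →
exclusion list → region, and each removed variant is audited with its first
failing rule. The MAF filter uses min(EAF, 1−EAF) since the effect allele
may be the major one. The region filter defaults to the HLA/MHC locus,
chr6:25–34 Mb (GRCh37), routinely excluded for its complex long-range LD;
variants without coordinates pass it silently. Confounder screening is a
user-supplied variant exclusion list (empty by default, which reproduces a
screening step that removed nothing). LD clumping is greedy on ascending
p-value (ties broken lexicographically by ID), so its output is independent
of input row order; missing r² pairs are treated as unlinked with a logged
warning.

Two instrument-strength statistics are exposed deliberately. The squared
Wald ratio (β/se)² is the per-variant default and is what published
per-variant F columns contain; the textbook variance-explained form
R²(N−k−1)/(k(1−R²)) with R² = 2β²·EAF·(1−EAF) gives much larger values for
a single variant in a large GWAS (≈497 vs ≈33 for the strongest bundled
row at N = 370,002). The two are not reconcilable per-variant and the
choice is explicit in the API.

The bundled 40-variant instrument table is shipped verbatim; it contains
one palindromic variant (rs2268023, A/T), which the loader surfaces with a
warning instead of silently dropping, since the table is a reference
artifact, not a recommendation.

## Harmonization

Allele pairs equal to the exposure's are kept; swapped pairs negate the
outcome beta and reflect its EAF; pairs that match after strand
complementation are treated as strand flips (standard practice);
palindromic variants are dropped by default because their strand cannot be
inferred from alleles alone (EAF-based retention is not attempted);
anything else is a mismatch. Retained records preserve exposure-file
order, and retained + dropped = shared, properties enforced by tests.
Outcome-side EAF may be missing; it is reporting-only.

## Synthetic data

Summary statistics are simulated directly — no individual-level genotypes —
because two-sample MR consumes nothing else and it keeps a full calibration
run desk-scale. For standardized traits, se = 1/√(2p(1−p)N) at allele
frequency p and sample size N; β̂_Xj ~ N(γ_j, se²_Xj) and
β̂_Yj ~ N(θγ_j + α_j, se²_Yj) with independent errors (non-overlapping
samples; an overlap parameter is a known extension, not implemented).
P-values come from the two-sided normal, alleles from the eight
non-palindromic ordered pairs unless palindromes are requested for
harmonization tests.

Defaults define the study conditions and were fixed once: 50 variants,
N = 100,000 per sample, MAF ~ U(0.05, 0.5), γ_j ~ N(0.08, 0.02²) — uniformly
strong instruments (per-variant F ≈ 200–400), matching the regime of a
well-powered GWAS exposure — θ = 0.1, and pleiotropy sd 0.004, the same
order as the outcome-side SE at N = 10⁵ so pleiotropy and sampling noise
compete realistically. The generator does **not** emulate LD between
variants (beyond what a supplied r² table injects in clump tests),
winner's-curse selection (instrument selection can be applied to simulated
data, but γ are drawn far from the significance boundary), binary-trait
liability-scale subtleties, or population stratification; passing
calibration here demonstrates correctness of the estimators under their
assumptions, not robustness to those real-data complications.

The MVMR generator shares one variant panel across K exposures, outcome
mean Σ_kθ_kγ_kj + α_j, with optional shared-confounder loadings that
correlate the exposures and open a backdoor path — used to demonstrate
that univariable IVW is biased under confounding where MVMR re-centers.

## Numerical and reproducibility choices

CIs use the normal 1.96 multiplier throughout (Egger and MVMR p-values use
t distributions, matching common reporting practice). Every stochastic
routine takes an explicit seed; the pipeline derives all per-outcome seeds
from the single study seed via seed-sequence spawning, so one seed yields
byte-identical output trees. Bootstrap default is 1,000 replicates.
Problem sizes in the calibration suite — 1,000 Monte-Carlo replicates for
coverage and the intercept-test level, 200 for MVMR bias and for
estimator-vs-oracle agreement — keep the Monte-Carlo SE of a coverage
estimate near 0.7 percentage points while a full run stays in the
tens-of-seconds range.

## Known limitations

* The weighted-median/mode parametric bootstrap double-counts the sampling
  noise already present in the observed ratios, so those SEs are mildly
  conservative (measured coverage ≈ 97% at nominal 95% under clean
  simulation conditions). The point estimates are exact against brute-force
  oracles.
* Wald-ratio SEs ignore exposure-side uncertainty (first-order delta); a
  weak-instrument regime would need the second-order term.
* No MR-PRESSO outlier correction, Steiger filtering, correlated-instrument
  IVW, MVMR-Egger, or conditional F diagnostics.
* LD handling consumes precomputed pairwise r²; proxy lookup and
  reference-panel computation are out of scope.
* Published instrument tables print rounded β/se, so recomputed per-variant
  F statistics agree with printed ones only to the propagated rounding
  error (max |ΔF| ≈ 0.006 across the bundled table), not digit-for-digit.
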