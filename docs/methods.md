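# Methods

## Model and notation

For J independent genetic instruments, the observed summary data are
(β̂_Xj, σ_Xj) from the exposure GWAS and (β̂_Yj, σ_Yj) from the outcome
GWAS, assumed drawn from non-overlapping samples. The working structural
model is

    β_Yj = θ β_Xj + α_j ,

where θ is the causal effect (log-OR of the outcome per unit exposure for
a binary outcome) and α_j is a direct ("horizontally pleiotropic") effect,
zero for a valid instrument. The three instrumental-variable conditions —
association with the exposure, independence from confounders, and no
outcome pathway other than the exposure — cannot all be tested from
summary data; the estimator battery spans different relaxations of the
third.

All per-SNP ratio estimates use θ_j = β̂_Yj/β̂_Xj with the first-order
(NOME) standard error σ_Yj/|β̂_Xj|, i.e. exposure coefficients treated as
measured without error. This is the standard convention when exposure
GWAS are much larger than the σ_X/β_X ratio would demand; a second-order
option adding σ_Xj²β̂_Yj²/β̂_Xj⁴ under the root is available
(`ratio_estimates(..., second_order=True)`) but is not used by the
estimators, whose weighting conventions are defined on the first-order
scale.

## Estimators

**IVW.** θ̂ = Σw_jβ̂_Xjβ̂_Yj / Σw_jβ̂_Xj², w_j = σ_Yj⁻²: weighted least
squares through the origin. Fixed-effects SE = (Σβ̂_Xj²σ_Yj⁻²)^−1/2. The
default multiplicative random-effects model inflates it by
max(1, √(Q/(J−1))), so heterogeneity widens but never narrows the
interval; the point estimate is identical under both models. Wald
p-values and CIs from the normal distribution.

**Penalized robust IVW.** Each weight is multiplied by
min(1, 20·p_j), p_j the upper χ²₁ tail of the SNP's heterogeneity
contribution at the plain IVW estimate, then the slope is refit by Huber
M-estimation (tuning constant 1.345, via statsmodels RLM) on the
weight-transformed regression. The SE is the penalized-weight analytic SE
with the same multiplicative scaling, computed at the robust estimate.
The penalty constant and tuning follow the robust-MR literature's
defaults; both are parameters. On exact-fit data the robust scale
degenerates, so a zero-heterogeneity short-circuit returns the (then
identical) IVW solution.

**MR-Egger.** The IVW regression with a free intercept, after orienting
every instrument to a positive exposure effect (done internally; ratios
are orientation-invariant, the intercept is not). The slope is consistent
under InSIDE (instrument strength independent of direct effects); the
intercept estimates the mean direct effect and tests directional
pleiotropy. SEs use multiplicative scaling max(1, √(RSS/(J−2))) and
inference uses t(J−2) — with few instruments the normal reference is
anti-conservative. Note a model-level caveat verified in simulation:
with strongly heteroskedastic σ_Yj and *additive* pleiotropy the
multiplicative overdispersion model is misspecified and the intercept
test over-rejects (≈9% at nominal 5% with σ_Y spanning 0.02–0.05); with
near-homogeneous σ_Yj it is calibrated (≈5.4%). This is a property of
IVW-weighted Egger regression, not of this implementation.

**Simple / weighted median.** The (weighted) median of θ_j; the weighted
version interpolates θ against the standardized cumulative weights
s_j = Σ_{k≤j}w_k − w_j/2 at s = 0.5, with w_j ∝ β̂_Xj²σ_Yj⁻². Consistent
when valid instruments hold >50% of the count (simple) or weight
(weighted). SEs from a parametric bootstrap (default 1000 replicates)
that redraws both β̂_Xj and β̂_Yj from normals at their observed values
with their reported SEs; deterministic given the seed.

**Weighted mode (MBE).** The argmax of the inverse-variance-weighted
normal-kernel density of the θ_j, bandwidth h = φ·0.9·min(sd*, mad*)·J^(−1/5)
with weighted SD and 1.4826-scaled weighted MAD (the modified Silverman
rule; φ = 1 by default, smaller φ is more robust and noisier). The argmax
is taken over a 512-point grid on [min θ − 3h, max θ + 3h]; exact ties
break to the smallest grid index, making the estimate deterministic. If
all ratios coincide the density is a point mass and that value is
returned. SE by the same parametric bootstrap. The bootstrap SE of a
mode is conservative: replicates perturb already-noisy ratios, widening
the empirical density by ≈√2 when true ratio heterogeneity is absent, so
CIs over-cover (measured ≈99.5% at nominal 95%, J=100; the mode-based
estimation literature reports the same behaviour). The package reports
it as-is rather than applying an ad-hoc deflation.

**MR-PRESSO.** Observed RSS = Σ_j (β̂_Yj − θ̂_(−j)β̂_Xj)²/σ_Yj² with
leave-one-out fixed-effects IVW predictions. The null distribution
redraws each SNP's betas from N(β̂_Xj, σ_Xj) and N(θ̂_(−j)β̂_Xj, σ_Yj)
and recomputes the leave-one-out RSS per replicate; the global p is the
Monte-Carlo tail (1+#{RSS* ≥ RSS})/(n_sim+1). Per-SNP tails on each
contribution are Bonferroni-adjusted across J; adjusted p < 0.05 flags an
outlier. Note the resolution constraint: the adjusted p can never fall
below J/(n_sim+1), so flagging anything at threshold τ requires
n_sim > J/τ − 1 (with J = 50 and τ = 0.05, n_sim = 1000 is the bare
minimum; the pipeline default is 1000 and larger values are recommended
for J ≳ 40). The corrected estimate is the headline IVW on the
non-flagged subset; the distortion test compares the raw-vs-corrected
shift against removing 1000 random subsets of the same size and is
reported but not used for gating. Under the null the standardized RSS
has expectation J + J/(J−1), not J: each leave-one-out prediction adds
estimation variance β̂_Xj²Var(θ̂_(−j))/σ_Yj² ≈ 1/(J−1) per SNP. The test
suite asserts this refined moment.

## Harmonization

Outcome records are matched by rsid; unmatched exposure SNPs are dropped
and reported ("not found in outcome"). Allele alignment tries direct
label match, swapped labels (flip β, complement eaf), then the same two
after strand complementation; residual mismatches are dropped with
reason "allele mismatch". Palindromic SNPs (A/T, C/G) default to
`infer_by_eaf`: orientation by which side of 0.5 both studies' effect
allele frequencies fall on, dropping SNPs with either frequency inside
the ambiguous window [0.42, 0.58] (threshold configurable); `drop` and
`keep` (same-strand assumption) policies are available. Every input SNP
receives exactly one disposition row in the harmonization report, and
kept + dropped always reconciles with the input count. Harmonization is
idempotent and per-SNP ratios are invariant under allele relabeling in
either study — both are property-tested.

Proxy-variant substitution for SNPs missing from the outcome is not
implemented (a documented limitation); LD independence of instruments
(r² < 0.20) is an assumed precondition on the inputs, since verifying it
needs genotype reference panels; the pleiotropy screen is consumed as a
user-supplied exclusion list rather than queried live, for
reproducibility.

## Synthetic data generator

`SimulationConfig` emulates the two-sample summary format directly: true
β_Xj ~ N(0.07, 0.02²) truncated to |β_Xj| ≥ 0.01 (weak-instrument
degeneracy in ratios is deliberately excluded), σ_Xj ~ U(0.004, 0.01),
σ_Yj ~ U(0.02, 0.05), θ = 0.3 by default — effect and noise scales
typical of a large quantitative-trait GWAS against a case-control
outcome GWAS of tens of thousands. Pleiotropy modes: `none`, `balanced`
(α ~ N(0, sd)), `directional` (α ~ N(mean, sd)) applied to the first
round(invalid_fraction·J) SNPs; `inside_violation` ρ correlates α with
instrument strength, α = mean + sd(ρ·z_X + √(1−ρ²)·z). Observed betas
add N(0, σ) noise. Draws are keyed per SNP index from the single seed,
so SNP j's values are independent of J. `simulate_study_tables` wraps
the same dataset in on-disk summary tables with random non-palindromic
allele labels and optional label scrambling that harmonization must (and
is tested to) undo exactly.

What the generator does **not** emulate: LD between instruments, sample
overlap between the two GWAS, winner's-curse selection of instruments,
allele-frequency-dependent power, population stratification. Passing
tests therefore demonstrate correctness of the estimators under the
stated structural model, not robustness to those real-data complications.

Scenario design used in validation (chosen as the regimes the respective
methods target): robustness orderings are evaluated with direct effects
several times the per-instrument ratio sampling noise (directional mean
0.2 or balanced sd 0.1 against a median ratio SE of ≈0.5 × θ-scale);
when pleiotropy is *smaller* than sampling noise, plain IVW's MAE is
competitive with or better than the robust estimators', which is
expected behaviour, not a defect. Egger-intercept calibration is
measured under near-homogeneous outcome SEs for the reason given above.

## Pipeline conventions

Per-method instrument minimums (IVW 1, Egger/medians/mode 3, MR-PRESSO
4) gate execution; skips are recorded with reasons and reconciled in the
run manifest (requested = run + skipped + failed). Estimates are
serialized at full precision; the formatted table rounds to 2 decimals
in the `OR(low-high)` style only in the display view. Significance is
annotated at two-sided p < 0.05 with no multiple-testing correction
across traits — a deliberate mirror of common practice in multi-trait MR
reports, and a caveat. Exposure-scale strings are labels only; the
pipeline never re-transforms trait units. A per-trait `flip_exposure`
flag negates β_Xj to report effects per unit *lower* exposure (used for
β-cell-function-style traits where the risk direction of interest is a
decrease).

## Numerical choices

z = Φ⁻¹(0.975) throughout Wald intervals; t(J−2) for Egger. Bootstrap
SDs use ddof=1. The penalized-robust short-circuit triggers at Q < 1e−12.
Collinearity in Egger (all β_X equal after orientation) raises an error
rather than returning an unstable fit. Monte-Carlo p-values use the
add-one (1+#)/(n+1) form, so they are never exactly zero and have
resolution 1/(n_sim+1). All stochastic routines take explicit seeds and
are bit-reproducible given them; the pipeline config requires a seed
whenever a stochastic method is requested.

## Known limitations

No multivariable or bidirectional MR, no colocalization, no
winner's-curse correction, no LD clumping or proxy lookup. The Egger
intercept test's calibration depends on the overdispersion model as
described. MBE intervals are conservative. MR-PRESSO's outlier test
loses all power when n_sim is too small for the Bonferroni floor —
checked and documented, but the responsibility for choosing n_sim ≫ J/τ
rests with the caller.
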