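# Methods

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generators emulate,
and the limitations a user should know about. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Quantile regression and the check-loss solver

All quantile fits minimize the check loss `Σ_i ρ_τ(Y_i − x_i'b)` with
`ρ_τ(u) = u(τ − 1(u<0))`. The default solver is a Frisch–Newton
primal–dual interior-point method (Mehrotra predictor–corrector on the
bounded-variable dual `max y'a s.t. X'a = (1−τ)X'1, 0 ≤ a ≤ 1`), the
standard algorithm for dense quantile regression at these problem sizes.
Termination is on the primal–dual gap at relative tolerance 1e-8;
initialization is deterministic (least squares for the primal,
`a = (1−τ)·1` for the dual), so all results are reproducible bit-for-bit.
A numba-compiled kernel is used when numba is importable; the pure-numpy
implementation is the fallback and the two agree to solver tolerance. An
exact LP path through `scipy.optimize.linprog` (HiGHS) is retained as an
independent cross-check and is exercised against the interior-point
solver in the test suite (objective agreement ~1e-9).

Intercept-only fits use the analytic solution: the lower-order-statistic
empirical quantile `Y_(⌈nτ⌉)`. When `nτ` is an integer the minimizer is
an interval; the lower endpoint is returned. In degenerate designs the
objective value, not the coefficient vector, is the contract.

## The rank-score test and regression rank scores

For variant j the score is `S = n^{-1/2} Σ_i G*_i φ_i` with `G*` the
dosage residualized on `[1, C]` (the intercept is always in the
projection so the score is mean-centered), and
`σ² = τ(1−τ)‖G*‖²/n` exactly. The null model is fitted once per
(gene, τ) and reused by every variant in the cis-window.

`φ` is taken from the dual of the quantile LP (Gutenbrunner–Jurečková
regression rank scores, `φ_i = a_i − (1−τ)`), not from the sign of the
fitted residual. The two coincide except on the ~q+1 observations that
sit exactly on the fitted hyperplane, where the dual takes interior
values chosen so that `X'φ = 0` holds exactly. This matters: with many
covariates the sign-function convention mis-scores those interpolated
points and inflates the extreme-τ tests (measured 8.4% rejection at
nominal 5% with 45 covariates, n=400); the dual scores restore
calibration (4.9%). This is also how the established rank-score QTL
implementations obtain their scores.

Per-level p-values are two-sided normal; two-sidedness before
combination is the package's choice (standard for QTL scans). The
Cauchy combination clips inputs to `[1e-15, 1−1e-15]` before the tangent
transform. Combined p-values of the 19 dependent levels are calibrated
in the rejection tail but are not uniform in the bulk (a known property
of the Cauchy combination under dependence); calibration claims in the
tests are therefore tail claims.

## Variance QTL contrast

The variance test aggregates `V = Σ_{τ<0.5} (S_{1−τ} − S_τ)` over the
mirrored pairs of the 19-level grid (τ=0.5 gets weight zero) and uses
the exact null covariance `Cov(S_a,S_b) = (min(a,b) − ab)‖G*‖²/n`, so
`z = V/sd(V)` needs no resampling. One modification proved necessary:
the indicator threshold is recentered by each variant's OLS mean effect,
`φ_i = τ − 1(r_i < β̂_j G*_{ij})`. The raw contrast cancels location
effects only to first order; with a skewed genotype distribution
(binomial dosages at MAF ≠ 0.5) a strong mean effect leaks in at second
order through the genotype third moment, which measured as ~50% type-I
error at nominal 5% for a β=0.8 location shift. Recentring restores
calibration (5.0% under that location shift, 4.75% under the global
null) while leaving scale-effect power unchanged. The statistic is
QUAIL-inspired — it targets the same tail-contrast estimand — and is
validated by calibration, not by equivalence to the QUAIL software.

## Interaction QTL

`Y ~ 1 + G + F + G×F + C` by OLS on the rank-based inverse-normal
transform of Y (Blom offset c=3/8, the package's choice among the
standard offsets). Variants
with MAF ≤ 0.05 are excluded. Direction classes: uncertain if the
genotype main effect is not nominally significant (p>0.05), else
amplifying/counteracting by sign agreement of main and interaction
effects.

## Hierarchical multiple-testing correction

Stage 1: per gene, the lead Bonferroni-adjusted p-value
(`min p × m_g`, capped at 1, with `m_g` the *testable* variant count);
BH across genes at FDR 5%. Stage 2: `t* = max` lead Bonferroni p among
significant genes; a pair is significant iff its gene is significant and
its within-gene Bonferroni p is `≤ t*`. The comparison is `≤`, not `<`:
under strict inequality the boundary gene's own lead variant would fail,
which cannot be the intent. Realized gene-level FDR is verified by
simulation in the acceptance suite (200 replicates, 40 genes, 10%
non-null).

## Heterogeneity characterization

Shared qQTL/xQTL pairs are split by a Chatterjee rank-correlation test
of per-quantile slope estimates against τ. Slopes come from full
quantile-regression refits (scores do not provide slopes); the default
characterization grid is τ = 0.10…0.90 in steps of 0.10 (9 levels), and
the simulation study uses the 19-level mapping grid restricted to
[0.10, 0.90] (17 levels) so that the genome-wide heterogeneity call is
attainable (with 9 points the one-sided asymptotic p cannot fall below
~4.5e-4). The tie-corrected ξ formula is used throughout; ties in the
ordering variable are broken by original index, never at random; the
test is one-sided (heterogeneity is a positive-dependence alternative).

A caveat the tests document explicitly: the asymptotic null `√n·ξ ~
N(0, 2/5)` assumes independent responses, but per-quantile slope
*estimates* form a smooth, strongly autocorrelated path in τ whose
correlation structure does not shrink with sample size. The test
therefore flags a pure location model far above its nominal level
(~45% at α=0.05 on the 9-level grid) while flagging scale models
essentially always; and its significance under a fixed data-generating
process grows without bound as the slope grid is made denser. Flag
rates should be read as comparative, not calibrated; the heterogeneity
index `log|sd(β̂)/mean(β̂)|` (sample sd; +inf when the mean is within
1e-12 of zero, −inf when sd is zero) is the scale-free complement.

## Quantile TWAS

Significant qQTL variants are greedily LD-pruned (r² < 0.8, best p
first), harmonized to the LD panel (match on chrom/pos, swapped alleles
flip z, strand-ambiguous A/T and C/G pairs dropped by default, indels
excluded), and jointly fitted over the 99-level grid. Genotypes are
standardized before training and the LD matrix is the correlation matrix
of the same standardized dosages, so the scales in
`Z_k = ω̂_k'z/√(ω̂_k'Σω̂_k)` are self-consistent (Z is invariant to
rescaling ω̂ anyway). Quantile regions: fixed = three 33-level thirds;
dynamic = agglomerative merging of adjacent levels by average Pearson
correlation of weight columns, with K (capped at 10, minimum region
width 3) chosen to maximize Newman modularity of the positively
thresholded similarity graph; for a single-variant gene column
correlation degenerates and sign agreement is used. All-identical
columns collapse to K=1. A near-singular quadratic form
(`ω̂'Σω̂ ≤ 1e-10`) falls back to `Σ + 1e-6 I`, logged. Gene-level
significance applies Bonferroni across the configured family
(per-context by default).

## Synthetic data

Genotypes are Binomial(2, MAF) draws (Hardy–Weinberg), covariates iid
standard normal. Phenotype models: `null`; `location` (`Y = βG + C'γ +
ε`); `scale` (`Y = (1 + sG)ε + C'γ`, s > −1/2 so the multiplier stays
positive for dosage ≤ 2; the per-quantile slope has the closed form
`s·Φ^{-1}(τ)·σ_ε` used by the recovery tests); `tail_specific` (a latent
binary context B with P(B)=π gates the effect, emulating a
carrier-subgroup mechanism; B is written to truth files); and
`interaction` (the iQTL model with F itself a Hardy–Weinberg dosage).
GWAS summaries follow an RSS-style generator: an AR(1) latent-Gaussian
panel thresholded to dosages yields Σ, and `z ~ MVN(Σμ, Σ)` with μ
proportional to a chosen direction; λ=0 is an exact null. The default
AR parameter is 0.6 (realistic local LD decay).

What the generators do **not** emulate: realistic allele-frequency
spectra, LD beyond AR(1)-like decay, non-Gaussian expression noise,
cohort covariate structure, or pseudobulk sampling noise. Passing tests
therefore demonstrate correctness of the statistics under their stated
models, not performance on real cohorts.

The fixture bundle plants 10 location (β=0.6), 5 scale (s=1.0), and
5 interaction genes among 50, at n=400 with 10 covariates. The scale
effect size was set by a power pilot: at n=400 under the hierarchical
correction a scale gene needs a combined p ≲ 2e-5 at its lead variant,
which s=1.0 delivers for ~93% of genes while leaving the mean strictly
unchanged (so the linear scan stays null on these genes by
construction).

## The Monte-Carlo study

Per replicate: `Y = βG·G + βF·F + βI·G·F + C'βC + ε` with n=400,
G ~ Binomial(2, 0.1), F ~ Binomial(2, 0.15), 45 N(0,1) covariates,
ε ~ N(0, 0.2667) (read as a variance, σ≈0.516; a flag treats it as an SD
for sensitivity analysis), βF=0, βG ∈ {0, 0.15, 0.3}, βI ∈ {0, ±0.1, …,
±0.8}. βC defaults to the zero vector (the covariates are projected out
of every statistic, so summaries are insensitive; an option draws βC
once from N(0, 0.1²)). Monomorphic genotype draws are redrawn with a
logged count. Each replicate is analyzed as iQTL, qQTL (19-level
Cauchy-combined), and xQTL; when the quantile test detects at the
loosest threshold in use, per-quantile slopes on the 17-level τ =
0.10…0.90 grid feed the Chatterjee test. "Strong amplifying" means
βG = 0.3 with same-sign βI ∈ {0.6, 0.7, 0.8}. Heterogeneity summaries
average the conditional fractions across amplifying cells; cells with
zero detections at a threshold carry no conditional fraction and are
excluded from that average. Replicate seeds spawn deterministically
from the master seed.

Problem sizes: the acceptance script runs the strong cells at 1000
replicates and the remaining amplifying cells at 300; the test suite
uses 300/200. These sizes keep Monte-Carlo error on the reported
percentages to roughly one point (binomial, pooled over cells).

## Known limitations

- The rank-score asymptotics degrade when `n·τ` is small relative to the
  covariate count; extreme grid levels are slightly conservative with
  many covariates.
- The vQTL recentring makes the variance test conditionally valid given
  an estimated mean effect; it is conservative for very large mean
  effects.
- Dynamic quantile regions instantiate an unpublished clustering scheme
  concretely (correlation linkage, modularity selection, K ≤ 10,
  minimum width 3); other instantiations are plausible.
- The Chatterjee heterogeneity call is comparative, not calibrated, for
  the reasons above; its genome-wide-threshold behavior is grid-density
  dependent.
- EOO treats the two tested-pair universes symmetrically and uses their
  intersection as T12; enrichment against an annotation treats the
  annotation as a pseudo-method over the same universe.
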