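# Methods

This note documents the statistical models implemented in `bloodmr`, the
synthetic study conditions they are exercised under, and the numerical
and design choices that were genuinely open.

## Two-sample design and notation

For J instruments and K exposures, β̂_Xjk (with standard error σ_Xjk) is
the per-SD association of SNP j with blood-cell trait k from the exposure
GWAS, and β̂_Yj (σ_Yj) its log-odds-ratio association with the disease
from an independent case-control GWAS. All estimators condition on the
harmonized matrices; exposure-side measurement error is ignored in ratio
weights (the NO Measurement Error assumption standard for these
estimators) — with exposure samples of ~563k individuals, σ_X/|β_X| is a
few percent for selected instruments, so the approximation is mild.

## Instrument funnel

- **Selection**: p < 5×10⁻⁸ in at least one exposure.
- **Proxying**: an instrument absent from the outcome panel is replaced
  (outcome side only) by the present SNP with maximal r² ≥ 0.8; the
  proxy's outcome record is aligned through the proxy's own exposure
  record, so its sign convention is consistent.
- **Clumping**: greedy by ascending minimum exposure p-value at
  r² > 0.001 on the pooled (all-trait) candidate set. No physical-window
  restriction is applied: synthetic LD is block-structured, so windows
  would be vacuous.
- **Confounder screen**: any catalogued association at p < 5×10⁻⁸ drops
  the SNP.
- **Harmonization**: rows reported on the swapped or strand-complement
  orientation have the effect sign flipped. Palindromic (A/T, C/G) SNPs
  are kept only when both minor-allele frequencies are below 0.42 and the
  frequencies identify the orientation; otherwise dropped (conservative
  convention).
- **Strength/power**: overall F = (R²/k)/((1−R²)/(n−k−1)); per-SNP
  F = (β/σ)². Power for a binary outcome uses the normal-approximation
  non-centrality Φ(|ln OR|·√(n·R²·v(1−v)) − z_{1−α/2}) with v the case
  fraction — the standard closed form for IVW power with summary data.

## Univariable estimators

With ratio estimates R_j = β̂_Yj/β̂_Xjk and weights w_j = β̂²_Xjk/σ²_Yj:

- **IVW**: θ̂ = Σ w_j R_j / Σ w_j (a weighted regression through the
  origin). Fixed-effect SE = (Σ w_j)^{-1/2}; the multiplicative
  random-effects SE multiplies it by max(1, √(Q/(J−1))) so heterogeneity
  never shrinks uncertainty. Normal reference for CIs and p-values.
- **Medians**: the *exact* (L1) weighted median — the smallest ratio whose
  cumulative weight reaches half the total, with the midpoint convention
  on exact ties. This choice (rather than the interpolated percentile
  variant found in some software) makes the estimator literally the
  minimizer of Σ w_j|R_j − c| : the dominance property (a SNP with >50%
  of weight is returned unchanged) holds exactly, and brute-force
  enumeration over candidate ratios is a machine-precision oracle. The
  penalized variant multiplies weights by min(1, 20·p_j) with p_j the
  χ²₁ tail of SNP j's Q contribution at the unpenalized estimate. Median
  SEs come from 1000 (configurable) seeded parametric bootstrap resamples
  of (β̂_X, β̂_Y).
- **MR-Egger**: weighted regression of β̂_Y on β̂_X *with* intercept after
  orienting all β̂_X ≥ 0; the intercept estimates directional pleiotropy,
  the slope is the pleiotropy-corrected effect. SEs are inflated by
  max(1, √(RSS_w/(J−2))) and referred to t(J−2) — the convention of the
  standard implementations; IVW uses the normal reference.
- **Cochran's Q** at any estimate: Σ w_j (R_j − θ̂)², χ²(J−1).

The Bonferroni threshold is α/(K·outcomes); at the defaults
(15 traits × 2 diseases) this is 0.05/30 ≈ 0.00167.

## MR-BMA

On the transformed scale y_j = β̂_Yj/σ_Yj, X_jk = β̂_Xjk/σ_Yj (no
intercept; residual variance fixed at 1 because the weighting already
standardises rows), a model m ⊆ {1..K} has marginal likelihood

  y | m ~ N(0, I_J + σ² X_m X_mᵀ),

with an independent N(0, σ²) prior on each included causal coefficient
(σ = 0.25 by default) and a Bernoulli(p = 0.1) inclusion prior, following
the published defaults of the method this stage implements. The posterior
is enumerated exhaustively over all non-empty subsets up to
`max_model_size` (default 12; with K = 15 the full 2¹⁵ space is feasible
by setting it to K). All subset quantities reduce to the K×K Gram matrix,
so enumeration cost is independent of J. MIP_k sums PP over models
containing k; θ̂_MACE,k sums PP·θ̂_λ,k (subset-specific weighted
least-squares estimates). Model tables are strictly PP-sorted.

**Pruning.** On every model with PP > 0.02, per-SNP Cochran Q
contributions (squared standardized residuals; their sum is the model's
Q) and classical Cook's distances are computed; a SNP exceeding Q > 10 or
Cd > median F(d, J−d) in any such model is dropped, and the posterior is
re-enumerated, up to `max_prune_rounds` (default 10). The rule, both
thresholds, and the "relevant F-distribution" interpretation
(d = offending model's size) are exposed in `BmaConfig`. Results before
pruning are retained alongside the final posterior as a consistency
check.

A behaviour worth knowing: with hard-zero sparse exposure effects (the
generator's Bernoulli masks), a singleton model's design column has only
~J·sparsity active entries, so leverage concentrates (hat values up to
0.3–0.5) and the median-F Cook's rule flags genuinely influential —
but valid — instruments in a substantial fraction of clean replicates;
checking several PP > 0.02 models multiplies such flags. Planted gross
outliers are always caught (by their Q contributions), but "nothing else
is ever flagged" should not be expected under sparse designs; the
validation module reports both the exact-recovery and the sensitivity
rate. Real blood-trait effect matrices are denser, which tempers (without
eliminating) this behaviour.

## Restricted-cubic-spline dose-response

Case status is modelled by logistic regression on a restricted (natural)
cubic spline of the trait: m knots give m−1 basis columns (linear plus
m−2 truncated cubics constrained to linearity beyond the boundary knots,
scaled by (t_m−t_1)²). Knots default to 4 at Harrell's quantiles
(5, 35, 65, 95%). The reported curve is the linear-predictor difference
from a reference value — the healthy-group median, so logOR is risk
relative to a typical healthy value — with a pointwise delta-method 95%
band; intercept and any covariates cancel in the contrast. Age/sex
adjustment is available behind a flag and off by default. Zero crossings
of either band boundary are located by linear interpolation on a
200-point grid and rounded to 2 decimals. Quasi-separation is detected
(non-finite SEs or |coef| > 50) and flagged rather than hidden. Group
comparisons use the Mann-Whitney U test with a direction flag given by
the sign of the median difference.

## Synthetic study conditions

The generator's defaults are the study conditions, chosen once:

- 15 exposures measured in 563,085 individuals; outcomes CD
  (5,956/14,927 cases/controls) and UC (6,968/20,464). Exposure SEs are
  1/√(2f(1−f)n); outcome SEs use the log-OR variance approximation
  1/√(2f(1−f)·n·v(1−v)) at the case fraction v; allele frequencies f are
  uniform on (0.05, 0.95) to avoid degenerate variances.
- Per-SNP effects: independent Bernoulli(sparsity = 0.1) masks per
  exposure applied to draws correlated across traits (exchangeable
  correlation 0.3, a middle ground for interrelated hematological
  indices), with per-allele effect SD 0.05. This scale puts the per-SNP F
  of selected instruments in the tens-to-thousands range reported for
  blood-trait instruments.
- Pleiotropy: 5% of SNPs carry a direct N(0, 0.02²) outcome effect —
  balanced, so IVW stays consistent while heterogeneity diagnostics have
  something to find.
- LD: block-diagonal with configurable block size and within-block r²;
  block-mates tag the index SNP's signal scaled by r, so proxy lookup is
  statistically coherent. SNPs withheld from the outcome panel
  (missing_frac = 0.1) keep at least one block-mate present.
- Cohort: lognormal CBC draws (healthy reference means/SDs from standard
  adult ranges) with disease-group shifts of ±0.8 healthy-SD on the log
  scale in the directions reported for active IBD (e.g. lower LYM in CD,
  higher EOS in UC); sizes 100/230/80.

What the generator does **not** emulate: realistic human LD maps, allele
frequency spectra by ancestry, genomic coordinates, winner's-curse-free
three-sample designs, or dense small effects of every SNP on every trait.
Passing tests therefore demonstrate correctness of the estimators and
pipeline logic under a controlled design, not performance on real GWAS
data.

## Problem sizes

The default pipeline run uses 1,500 SNPs in blocks of 3 (≈ 350
instruments after clumping — the same order as the ~900-instrument real
analysis), and the validation experiments use 150-instrument
multivariable sets (K = 8), 100 replicates for recovery/pruning rates,
1000 null and 200 alternative replicates for IVW calibration, and
25 replicates for spline coverage. These sizes give Monte-Carlo errors
of a few percent on the reported rates.

## Known limitations

- NOME ratio weights (above); no Steiger filtering, MR-PRESSO or
  contamination-mixture estimators — only the six named methods.
- MR-BMA enumeration is exhaustive; no stochastic search for K > 20.
- The median-F Cook's pruning rule is aggressive under sparse synthetic
  designs (see MR-BMA section).
- The spline stage fits marginal, unadjusted curves by default, matching
  the descriptive use it supports.
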