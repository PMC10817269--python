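# Methods

## The composite score

The evaluation ranks T treatments measured on p traits with r replicates
each. Replicates are averaged (mean ± SE, SE = sample SD/√n with the n − 1
denominator) into a T × p mean matrix. Because traits carry incommensurate
units, the analysis standardises each trait column to zero mean and unit
sample variance and works with the trait **correlation** matrix; covariance
PCA would let whichever trait has the largest numeric scale dominate.

With Z the standardised matrix and (λ_j, v_j) the eigenpairs of
R = ZᵀZ/(T − 1):

- **comprehensive index** CI_j = (Z v_j)/√λ_j — component scores rescaled so
  every CI column has sample variance exactly 1 (the factor-score
  convention; the published table this package reproduces follows it, as
  each of its printed CI columns has sample SD 1.000 within rounding);
- **contribution rate** P_j = 100·λ_j/p (Σλ = p for a correlation matrix, so
  rates sum to 100 over all components);
- **membership** μ(X_j) = (CI_j − CI_min)/(CI_max − CI_min), computed
  column-wise across treatments, so the worst treatment on a component
  scores 0 and the best 1;
- **weights** W_j = P_j/Σ_j P_j over the retained components only;
- **D value** D = Σ_j μ(X_j)·W_j, in [0, 1] when ΣW = 1, ranked descending
  with competition ("1224") ranking on ties.

D is invariant under any strictly increasing affine transform of a CI
column (min–max normalisation absorbs it), and monotone: raising one
treatment's index within the column range never lowers its D. Membership is
relative to the treatment set in the run — adding or removing a treatment
moves the column extremes and changes every μ and D. That is inherent to
the method and users comparing runs must keep the treatment set fixed.

### Conventions where the method is underdetermined

- **PCA input.** The PCA runs on the T × p treatment-mean matrix, not on
  replicate-level data: the composite assigns one index value per
  treatment, and replicate noise is already collapsed by the averaging
  stage.
- **Eigenvector signs.** Eigenvectors are defined only up to sign, and the
  sign propagates into μ and D. `pca()` fixes each component so its
  largest-magnitude loading is positive (ties: lowest trait index). On its
  own that rule can still point a component *against* performance — whenever
  the dominant loading happens to belong to a cost-type trait. The
  end-to-end evaluation therefore negates cost-trait columns (declared via
  the benefit/cost orientation flag in the input schema) after
  standardisation, so that every trait, hence every component under the
  sign rule, points toward better performance and a higher D means a more
  tolerant treatment. This is why the orientation flag is mandatory in the
  schema: it cannot be inferred from the numbers.
- **Component retention.** Default policy is a fixed k = 3; Kaiser (λ > 1)
  and a cumulative-contribution threshold are available. Under the
  cumulative policy the retained count is the smallest k reaching the
  threshold, so a rank-deficient matrix (more traits than treatments) never
  retains zero-variance components even at threshold 100%.
- **Weight source.** Weights are recomputed from contribution rates by
  default (they then sum to 1 exactly). A `supplied` mode accepts weights
  from a printed table; published weights are typically rounded, so the sum
  is only required to lie in [0.98, 1.02]. Reproductions of printed D
  columns should use supplied mode with the printed weights — recomputed
  weights can differ from printed ones in the third decimal (e.g. 0.773 vs
  a printed 0.770) and shift D by a few thousandths.
- **Display rounding** is 3 decimals in `summary()`; internal values keep
  full precision.

## Two-group effect statistics

Treatment-vs-control reporting uses the signed percent change of means,
100·(treatment − control)/control, plus a two-sided test:

- **Exact rank-sum** (default when both groups have ≤ 8 values): the pooled
  values receive midranks; all C(n_a + n_b, n_a) assignments of those
  midranks to group a are enumerated and the two-sided p is the fraction
  whose rank-sum deviates from the null mean by at least the observed
  deviation. With ties the enumeration simply reuses the observed midranks.
  Note the granularity floor: at 3 vs 3 the smallest achievable two-sided p
  is 2/20 = 0.1, so starred significance at n = 3 necessarily comes from an
  asymptotic approximation or a t test.
- **Asymptotic rank-sum**: normal approximation with the standard tie
  correction and no continuity correction (matching common
  statistics-package defaults).
- **Student's t**: pooled-variance two-sample form; Welch available via
  `welch=True`. Two constant groups with different means are flagged
  degenerate (the t statistic diverges); identical groups return p = 1 with
  a degenerate flag.

Stars follow the strict thresholds p < 0.05 (*), < 0.01 (**), < 0.001 (***).
No multiple-testing correction is applied — the module mirrors single-trait
reporting conventions.

## Relative expression (2^−ΔΔCt)

For target and reference genes with replicate Ct values, ΔCt_r = Ct_target,r
− Ct_ref,r per replicate; ΔΔCt_r subtracts the mean control ΔCt; the fold
change is the arithmetic mean of the per-replicate 2^−ΔΔCt values with its
sample SE (the "mean ± SE of fold changes" convention). The alternative
2^−(mean ΔΔCt) — the geometric form, equal to the default only when
replicates agree exactly — is available as `aggregate="mean_ddct"`.
Amplification efficiency is fixed at 2 (the Livak assumption); no
standard-curve correction. Fold changes are invariant to any global Ct
shift, and swapping treated and control inverts the fold exactly when
replicate ΔCt values are degenerate.

## DEG screening

A gene is differentially expressed when |log2FC| ≥ threshold (default 2,
boundary inclusive), optionally AND adjusted p < α — off by default, since
fold-change-only screens are common and the α used by any given study is
often unstated. Direction follows the sign of log2FC. Overlaps of DEG id
sets report shared/only-a/only-b tallies.

## Synthetic data

The trait generator draws value(t, r, trait) = baseline + sign·effect·scale·δ_t
+ ε with ε ~ N(0, (σ·scale)²); `sign` is +1 for benefit and −1 for cost
traits. Defaults emulate a realistic screening design: 9 treatments (8
strains + control "CK") × 18 traits × 3 replicates; a trait panel patterned
on a drought-physiology measurement set (two water contents, four
gas-exchange parameters, and shoot/root osmolytes, MDA, CAT, POD, SOD, with
MDA and CAT cost-typed); planted tolerance δ evenly spaced from 1 down to 0
(control); effect size 1 scale-unit per unit δ; replicate noise σ = 0.05 of
the trait scale, comparable to the few-percent standard errors typical of
n = 3 physiology panels. A second, δ-independent latent factor
(`n_factors=2`) loads on alternate traits to give the mean matrix rank > 1
and exercise multi-component retention; `heavy_tailed=True` swaps Gaussian
replicate noise for t(3) to exercise the rank tests. All generators are
pure functions of (config, seed).

What the generator does **not** emulate: the empirical covariance structure
of real trait panels (beyond one or two planted factors), trait-specific
noise distributions, replicate-level outliers, or any biology linking the
traits. Passing recovery tests therefore demonstrates that the pipeline's
algebra is correct and that its ranking degrades gracefully with noise —
not that the composite score is biologically optimal for any particular
dataset.

The Ct generator inverts the Livak formula (treated target Ct shifted by
−log2(fold)), so at σ = 0 the pipeline recovers planted fold changes
exactly; the DE-table generator places planted DEGs at least `margin`
(default 0.5) beyond the threshold and null genes at least `margin` below
it, so the screen recovers planted counts exactly.

## Problem sizes and numerical choices

The packaged reproduction operates on the 9 × 3 published index table and
runs in milliseconds. Recovery sweeps use the default 9 × 18 × 3 design
over 200 seeds and three noise levels (σ ∈ {0.05, 0.5, 2.0}) in the
acceptance suite and 60 seeds in the unit suite — Monte-Carlo sizes chosen
so the mean-correlation trend is stable (assertions allow 0.02 slack for
Monte-Carlo error). Degenerate inputs fail loudly rather than silently:
zero-variance traits abort standardisation naming the trait, zero
eigenvalues abort index construction, constant CI columns abort membership
naming the component, and a missing reference gene aborts the qPCR
computation naming the (group, replicate).

## Known limitations

- No uncertainty interval on D (no bootstrap over replicates); the score is
  a point summary.
- The exact rank-sum enumerates C(n_a + n_b, n_a) assignments and is
  intended for the small-replicate regime (≤ 8 per group by default).
- PCA requires a complete mean matrix; missing values are rejected, not
  imputed.
- The qPCR module assumes a single reference gene and fixed efficiency 2;
  no multi-reference normalisation or standard-curve correction.
- The DEG module screens existing differential-expression tables; it does
  not fit count models itself.
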