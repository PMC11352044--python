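# Methods

## The quantity under study

For a variable measured in a reference group `a` and a treatment group `b`
(strictly positive values), every fold-change (FC) convention in use reduces
to a log2 ratio of two group *expected values*,

    logRatio = log2 E[b] − log2 E[a],

mapped to a signed symmetric fold

    FC = 2^logRatio            if logRatio ≥ 0
       = −2^(−logRatio)        otherwise,

so +3 means "three times up" and −3 means "three times down", with FC = 1
at logRatio = 0.  The estimators differ only in the definition of E[·]:

| method               | expected value                                      |
|----------------------|-----------------------------------------------------|
| `LOG_OF_MEANS`       | arithmetic mean                                     |
| `LOG_OF_MEDIANS`     | median                                              |
| `MEAN_OF_LOGS`       | geometric mean (mean of log2 values; alias `GEOMETRIC_MEAN`) |
| `MEDIAN_OF_LOGS`     | median of log2 values                               |
| `PAIRS_MEAN`         | mean of log2(b_i/a_j) over all ordered cross pairs  |
| `PAIRS_MEDIAN`       | median of log2(b_i/a_j) over all ordered cross pairs|
| `PAIRS_*_BOOTSTRAP`  | the same pair aggregates on groups resampled with replacement, averaged over replicates |

Two algebraic identities matter.  First, the Cartesian pairs mean equals
the difference of log means exactly, so `PAIRS_MEAN` ≡ `MEAN_OF_LOGS`; the
package computes the pairs form by explicit enumeration below 10^6 pairs
and by the identity above it, and a property test checks the two routes
agree.  Second, on log-normal data `LogNormal(µ, σ)` the arithmetic mean is
`exp(µ + σ²/2)` while the median and geometric mean are `exp(µ)`; hence the
log-of-means estimate converges to

    log2(fc_true) + (σ_b² − σ_a²) / (2 ln 2)      [bits]

while all median/geometric-mean-based estimators converge to
`log2(fc_true)`.  This closed form is the oracle for the variance-sweep
experiment and the source of every qualitative conclusion about the
arithmetic-mean method's fragility.

Recovery of a known ratio is scored on the signed fold scale:

    ErrorFC = signedFold(FC_calculated) − signedFold(FC_true),

which is zero iff the two agree and antisymmetric in its arguments.  Note
one intrinsic degeneracy: `signedFold` maps ratios in (0, 1) to (−∞, −1]
and ratios in [1, ∞) to [1, ∞), leaving a gap between −1 and +1.  At
`fc_true = 1` any sampling noise pushes the estimate across the gap and
produces an O(2) error even for an unbiased estimator; grids therefore
avoid placing a cell exactly at FC = 1, and tests judge the boundary cell
on the log-ratio scale instead.

## Numerical choices

- Log base 2 throughout, including inside the mean/median-of-logs
  estimators.
- Zeros and negative values are a hard error for every estimator (fold
  change is a ratio of positive quantities); no pseudo-count option is
  offered.  Matrix-level analyses skip variables flagged
  `contains_nonpositive` and report them in an `excluded` table.
- Median of an even-length vector: midpoint of the two central order
  statistics.
- Pairwise aggregates use the *full* Cartesian product at every n.  Above
  10^6 pairs the median is found by a value-space selection on the two
  sorted log vectors (bisection with an exact vectorised pair count per
  pivot), locating the central order statistics to 1e-11 relative without
  materialising the pairs; inside bootstrap replicates the tolerance is
  relaxed to 1e-7, far below the resampling noise that the replicate
  average integrates over.
- Bootstrap variants resample `a` and `b` independently with replacement to
  their original sizes and average the replicate aggregates;
  `bootstrap_reps` defaults to 100.  The replicate count and resampling
  unit are package conventions (reasonable defaults, not a published
  protocol).
- Box-Cox λ is the maximum-likelihood value on [−3, 3]
  (`scipy.stats.boxcox_llf` with bounded scalar minimisation), snapped to
  Tukey's ladder {−2, −1, −1/2, 0, 1/2, 1, 2} with equidistant ties broken
  toward 1.  Normality is judged by Shapiro–Wilk at α = 0.05 on raw and
  log2 values.  With a small coefficient of variation the Box-Cox
  likelihood is nearly flat in λ (the transform is locally affine), so
  single-draw ladder labels on near-normal data are noisy; tests therefore
  assert the replicate-median label.
- The t test defaults to the Welch unequal-variance form — unequal
  variances are the whole point of the benchmark — with a pooled option.
  The Wilcoxon–Mann–Whitney test uses scipy's rank-sum with tie
  correction (exact enumeration where scipy selects it).  Constant pooled
  data yields p = 1 with a degeneracy flag rather than an exception.  No
  multiple-testing correction is applied anywhere by default; a
  Benjamini–Hochberg helper exists but is opt-in.

## Synthetic data

`SimSpec` fixes a family, a reference location `m_a`, a true ratio
`fc_true` (treatment location `fc_true · m_a`), spreads `s_a`, `s_b`
(measurement units for the normal family, natural-log scale for the
log-normal family), group sizes, and a seed; regeneration is bit-identical.
Families:

- identity — constant vectors;
- uniform — `U(0,1) · m` per group;
- normal — `N(m, s)`;
- log-normal — `LogNormal(ln m, s)`, so `fc_true` is the ratio of medians
  (equivalently geometric means), *not* of arithmetic means;
- the two asymmetric cross-family variants (one group normal, the other
  log-normal), which are what break the arithmetic-mean estimator even at
  equal nominal spreads;
- a fully mixed family drawing each element's family uniformly at random.
  Because the same mixture governs both groups, the mean inflation cancels
  in the ratio and all estimators remain consistent on this family — the
  asymmetric rows, not this one, carry the fragility result.

Defaults for the single-variable experiments: `m_a = 100` (keeps normal
draws positive with overwhelming probability at `s = 10`), `s = 10` for
normal groups, `s = 1` (log scale) for log-normal groups, small-sample
condition `n = 10`.

Panels draw per-variable parameters uniformly from fixed ranges
(log-normal: m ∈ [30, 40], s ∈ [1, 5]; normal: m ∈ [500, 600],
s ∈ [20, 200]) and true ratios log-uniformly from [1/3, 3] (log-uniform so
up- and down-regulation are symmetric in fold units; the sampling law for
the ratio is a package choice).  Panel group sizes default to 50 + 50.
With normal spreads up to 200 at locations near 500, a minority of
variables draw a non-positive value at n = 100; they are excluded from
log-domain analyses and counted, mirroring how such variables would have to
be handled in practice.  The matrix emulation of a multi-omics cohort uses
d = 680 variables with 50 reference and 95 treatment samples and a random
normal/log-normal family per variable.

The permutation stress flattens the whole matrix, shuffles all entries with
a seeded generator, and reshapes — destroying variable and sample structure
while conserving the value multiset (hence pooled moments) exactly.  Global
entry shuffling, rather than independent row/column reordering, is used
because only it changes per-variable distributions (reordering rows or
columns whole would leave every variable's values intact).

What the generators do **not** emulate: count noise (no negative-binomial
RNA-seq model), batch effects, missingness, or variable–variable
correlation.  Passing tests show estimator behaviour under the stated
sampling models, not performance on any particular real cohort.

## Experiments and their problem sizes

All stochastic cells are means over `reps` seeded replicates (default 25),
and every cell row records its full `SimSpec` and seed, so any cell can be
recomputed independently; run-twice determinism is under test.

- **Distribution stress**: 7 families × fc grid × n ∈ {10, 10,000} ×
  8 estimators.  The acceptance check runs fc = 2 at n = 10,000 with
  25 replicates; the unit suite uses n ≤ 2,000 with 3–5 replicates.  The
  re-log variant log2-transforms the generated data before estimation;
  there only rank preservation across the fc grid is asserted (the
  magnitudes no longer mean times-expression), and data that go
  non-positive under the first log (e.g. uniform draws below 1) become
  per-cell failure records.
- **Variance sweep**: fc on 20 points spanning [0.1, 6] × spread ratios
  {0.1, 0.5, 1, 2, 4, 8} × s_a ∈ {0.1, 1}, log-normal, n = 10,000,
  25 replicates, non-bootstrap estimators by default.  OLS trend lines of
  ErrorFC against fc_true are fitted per (method, s_a, ratio) panel.  The
  closed-form bias regression restricts to cells with σ ≤ 1 because the
  sample mean of a log-normal with σ much above 1 has not remotely
  converged at n = 10,000 (its summands' variance grows like e^{σ²}), so
  those cells measure sampling chaos rather than the asymptotic offset.
- **Significance panels**: d = 99 variables per family, 50 + 50 samples,
  all estimators × both tests, Spearman ρ of |log2 FC| against −log10 p
  and against |log2 fc_true|.  Crossover variables are those whose
  regulation direction differs between `LOG_OF_MEANS` and `MEAN_OF_LOGS`
  with both |log2 FC| > 0.1 bits — the threshold suppresses sign flips of
  estimates at numerical zero and is a package convention.
- **Permutation stress**: any matrix + labels; reports pooled
  skewness/kurtosis, the method × method Spearman matrix of |log2 FC|, and
  each method's correlation with both tests' significance.  The d = 680
  emulated cohort shape runs in minutes on one core.

## Known limitations

- The sign behaviour of the arithmetic-mean error in unequal-variance
  log-normal panels follows the closed form: the estimated ratio is
  `fc · exp((σ_b² − σ_a²)/2)`, uniformly below the truth when σ_b < σ_a
  and uniformly above it when σ_b > σ_a.  What reverses at FC = 1 is the
  *trend direction* of error versus fc (the fitted slope flips sign), not
  the sign of the error itself; the suite asserts both the uniform error
  sign and the slope reversal.
- Real-cohort normality percentages and permuted-matrix moment values
  depend on the unpublished cohort and on the (unnamed) normality test
  behind them; the Box-Cox/ladder and permutation machinery is validated
  on synthetic panels instead.
- Fold change is treated strictly as a ratio; difference-based "fold"
  semantics, shrinkage/moderated estimators, and missing-value handling
  are out of scope.
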