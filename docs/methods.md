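# Methods

## Problem and model

The package classifies subjects into two groups (e.g. a patient group
vs. controls) from resting-state functional-connectivity (FC) patterns.
The input per subject is a `T x R` matrix of ROI-averaged signals
(`T` time points, `R` regions; the reference cohort shape is `R = 116`
regions and `T = 180` volumes).

**Low-order network (level 0).** `C(0)_ij = corr(x_i, x_j)` — the
Pearson correlation between the time courses of regions *i* and *j*.

**High-order networks (levels 1..t).** Level `k + 1` correlates *FC
profiles* of level `k`: with `c_i` the *i*-th row of `C(k)`,

```
C(k+1)_ij = corr(c_i \ {i,j},  c_j \ {i,j})
```

where `\ {i,j}` removes the entries at positions *i* and *j* from both
rows, so a profile never contains the two regions being compared.  The
same exclusion rule is applied at every level of the recursion (the rule
is only forced at level 1; applying it uniformly keeps every level's
definition identical).  Diagonals are set to 1 at every level so each
matrix stays a valid correlation-like matrix; only the strictly-lower
triangle (`d = R(R-1)/2` entries, 6670 at `R = 116`) is ever used as
features.

**Feature selection.** Per level, LASSO on z-scored edge features:
`min_w 1/2 ||k - Xw||^2 + lambda ||w||_1`, labels `k` coded +1/-1.
`lambda` is kept on this un-normalised scale so the conventional grid
`{0.1, ..., 0.6}` retains its meaning; the LARS solver's `1/(2N)`
convention is rescaled internally.  Note that on this scale the grid is
a weak penalty for cohort-sized problems (`lambda_max = max_j |X_j^T k|`
is of order `N`), so the practical effect of selection is to cap the
active set at roughly the sample size — a real reduction from several
thousand edges, and the regime in which the selection-frequency analysis
operates.  A feature counts as selected when `|w_j| > 1e-8`.

**Classification.** One linear soft-margin SVM per level (cost parameter
`C`, grid `2^-5 .. 2^5`) on that level's selected features.  Decision
scores are fused linearly with non-negative weights summing to one
(two levels: `(a, 1-a)`, `a` in `{0.1..0.9}`; three or more: all grid
tuples normalised to the simplex, deduplicated); the fused score is
thresholded at zero, with an exact zero breaking to the positive class.
If a level selects zero features it degrades to a majority-class
constant with decision score 0.

**Tuning and evaluation.** Hyper-parameters `(lambda, C, fusion
weights)` are tuned by an inner stratified cross-validation run on the
training side of each outer fold only; every stage (standardisation,
selection, SVM) is re-fit inside each inner fold.  The winning grid
point maximises mean inner-fold accuracy, with deterministic tie-breaks
(smaller `lambda`, then smaller `C`, then weights closest to uniform).
`lambda` and `C` are shared across levels within one grid point — the
natural reading of a single joint grid search, and the option that keeps
the search tractable; the per-level values recorded in the trained
ensemble therefore coincide.  The outer protocol is stratified 10-fold
CV repeated 20 times (repetition `r` partitions with seed
`base_seed + r`).  Metrics: ACC, TPR, TNR, PPV, NPV, F1 from the fold's
confusion counts; a 0/0 ratio is recorded as undefined and excluded from
averages with a logged count.  Configurations run on identical
partitions are compared with a two-tailed paired t-test over per-fold
accuracies, pooling all repetitions (200 pairs at the defaults); pairing
at the fold level rather than on repetition means was chosen because it
uses the full information in the matched partitions.  Edge importance is
the count of outer fits in which an edge received a nonzero LASSO
weight, ranked per level with lexicographic tie-breaks.

## Synthetic cohorts

The generator emulates a two-group resting-state cohort: 54 positive
vs 46 control subjects, `R = 116`, `T = 180`.  Each subject's series is
`T` i.i.d. draws from a zero-mean multivariate normal whose correlation
matrix is the subject's *group target*, plus i.i.d. Gaussian observation
noise (sd 0.2).  Targets have 5 contiguous modules with within-module
correlation 0.3 and between-module 0.05.  Two planted mechanisms create
group differences:

- **edge deltas** (low-order effect): listed edges are shifted in the
  positive group's target; the preset plants five cross-module edges.
- **module reassignment** (high-order effect): listed ROIs have their
  membership blended toward the neighbouring module in the positive
  group (`C_pos = (1-b) C_base + b C_moved`).  Because correlation
  normalises away amplitude, a partial blend rotates the ROI's whole
  connectivity profile while moving each individual edge by only
  `b * (0.3 - 0.05)` — a contrast that is diffuse and weak edge-by-edge
  but concentrated at the profile-similarity (high-order) level.

Effect sizes in the presets were fixed once from the design requirement
that the planted contrasts be *moderate*: within-group variability is
pure estimation noise (all subjects of a group share one target), so an
edge delta is detectable roughly in proportion to
`delta * sqrt(T) / (1 - r^2)`, and deltas far above ~0.1 saturate
classification at `T = 180`, leaving nothing for a second level to add.
The presets use a 0.04 edge delta and a membership blend of strength
0.1 over 40 ROIs, which place single-level accuracies in the 0.7–0.85
range where level complementarity is observable.

Perturbed targets that leave the correlation cone are repaired by
nearest-correlation-matrix projection (error if any entry moves by more
than 0.05).  Known simplifications, hence what passing tests do *not*
show about real rs-fMRI: no temporal autocorrelation (Pearson FC depends
only on the cross-sectional covariance), no subject-level heterogeneity
within group, no hemodynamics, motion, or scanner drift, and Gaussian
margins.  Observation noise of sd `s` attenuates every off-diagonal
correlation by `1/(1 + s^2)`; the convergence check in the test suite
compares group-mean empirical matrices against the attenuated target,
since the entry-wise maximum over 6670 edges of single-subject sampling
noise alone (~4 sd at `T = 5000`) already approaches the 0.05 band.

## Numerical choices

- All correlation arithmetic in double precision; matrices are computed
  on one triangle and mirrored, so symmetry is exact.
- The high-order step uses closed-form exclusion corrections on
  row-centred sufficient statistics (`O(R^3)` per level); pairs whose
  reduced-profile variance falls below `1e-3` of the row's scale are
  recomputed from explicitly materialised profiles to avoid cancellation
  (agreement with a literal delete-and-correlate loop is then ~1e-14).
- A reduced profile with (numerically) zero variance yields entry 0 with
  a logged warning — "no evidence of similarity" — never NaN.
- Constant feature columns z-score to 0 (std treated as 1).
- Stratified fold draws that produce a single-class training side are
  redrawn with shifted seeds (hard error after 10 attempts); fold counts
  are capped at the minority-class size.
- SVM training tolerance 1e-10 so decision values are comparable to a
  quadratic-programming oracle at 1e-6.

## Scaling of the shipped checks

The test suite and the reproduction script run the full protocol at
reduced problem sizes chosen as the package's own defaults for desk-scale
verification: fewer repetitions (1–2 instead of 20), inner 5-fold instead
of 10-fold tuning, and compact hyper-parameter grids.  The cohort shape
itself (100 subjects, 116 ROIs, 180 time points) is never reduced in the
calibration and recovery checks.

## Known limitations

- LASSO drops members of correlated feature groups; selection
  frequencies understate the importance of edges correlated with
  selected ones (no elastic-net or stability-selection remedy).
- Decision scores are fused raw, with no per-level normalisation; levels
  whose SVMs produce systematically larger margins can dominate at equal
  weights.
- The inner search optimises accuracy only.
- High-order networks are deterministic functions of the low-order
  matrix, so level complementarity is representational (what a sparse
  linear pipeline can exploit at a given sample size), not informational.
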