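# Methods

## Model

`convexgsca` estimates path-analytic models among *components* — weighted
sums of observed indicator blocks. With indicators `z` (J × 1) and components
`γ = W'z` (P × 1), the model stacks three sub-models:

```
γ = W'z                      weighted relation
z = c0 + C'γ + ξ             component measurement
γ = b0 + B'γ + ζ             structural
```

Each component is either **convex** — its weight column satisfies
`1'w_p = 1` (optionally `w_p ≥ 0`) and its indicators keep their original
scale — or **standardized** — its indicators are standardized and the column
satisfies `w_p' S_p w_p = 1`. A convex component's scores are convex
combinations of its indicators, so scores, means and SDs all live inside the
indicators' own range: a satisfaction component built from 1–10 items has a
mean like 7.1 that reads directly on that scale, its weights are
contribution rates, and a path coefficient of a convex predictor is the
expected change in the outcome per unit change in *all* of its indicators.

Writing `V = [I_J, W]`, `A = [C, B]`, `a0 = [c0; b0]`, the estimator
minimizes the penalty-weighted sum of error variances of the dependent
variables,

```
f(W, A, a0) = E( SS( (u' − (a0' + z'WA)) O ) ),   u = [z; γ],
```

where `O = blkdiag(O_z, O_γ)` is diagonal: a dependent variable's entry is
the reciprocal of the *average sample SD of its block* (1 for standardized
blocks), zero for non-dependent variables. The penalty stops blocks on large
scales (a 0–50 percentage item next to 1–10 Likert items) from dominating
the fit, while deliberately *not* differentiating indicators within a block
— within-block variance differences are information the method wants to use.
"Dependent" means having at least one incoming arrow: all indicators (their
loadings are always estimated — a reflective measurement specification) and
every component with an incoming path.

## Estimation

Everything is computed from first and second moments. With `M = V − WA`,
the optimal intercepts are `a0 = M'μ` and

```
f = Σ_t o_t² [ ((M'μ − a0)_t)² + (M'SM)_tt ].
```

Hence a `MomentSet` (μ, S with the N−1 denominator, N) is sufficient:
fitting raw rows and fitting their exact moments give identical estimates.
The expectation convention makes the raw-data sum of squares `(N−1)·f` once
intercepts absorb the means; the scale does not affect any minimizer or any
fit index (all are ratios).

Alternating least squares cycles two exact conditional minimizations:

1. **A, a0.** The penalty is diagonal, so each dependent variable's equation
   separates; its free coefficients solve the regression of the variable on
   its predictor components (`(W'SW)_FF a = (W'S v_t)_F`), and the intercepts
   solve the mean equation. The penalty entry scales the residual, not the
   minimizer.
2. **One weight column at a time**, in declaration order, with intercepts
   profiled out. The objective is an exact quadratic in `w_p`
   (`quad·w'S_bb w + 2c'w + const`). Sum-to-one columns solve the single
   equality-constrained KKT system. Unit-variance columns minimize the
   linear term on the ellipsoid `w'S_bb w = 1` — equivalently the
   unconstrained solve renormalized, which is the exact constrained
   minimizer because the quadratic term is constant on the constraint set.
   With non-negativity on, the simplex-constrained solution is found by an
   exact active-set enumeration (block sizes are small), checking primal
   feasibility and multiplier signs.

Every step is an exact minimization over its block of variables, so the
objective trace is non-increasing by construction; iteration stops when the
absolute objective change falls below `tol` (default 1e-5) or at `max_iter`
(default 1000, flagged rather than raised).

**Initialization.** Equal weights per block (normalized to unit component
variance for standardized blocks) — deterministic, so golden tests are
exact. Optional seeded random multistarts draw Dirichlet(1) weights on the
simplex (convex) or normalized Gaussians (standardized); the best final
objective wins. Bootstrap replicates warm-start from the full-sample
solution.

**Degeneracies.** A convex block whose indicators are linearly dependent is
rejected (the weights would not be identified — a sum-to-one weight vector is
otherwise unique for a given score vector). Singular normal equations
elsewhere (e.g. a standardized block of perfectly correlated indicators,
where any direction on the constraint set is optimal) fall back to a
ridge-regularized solve with a warning; this reproduces the symmetric
equal-weight solution in the two-identical-tests example. Partial scale
invariance holds exactly: rescaling any block affinely (same positive factor
for the whole block) leaves all weight estimates and the minimum objective
unchanged, with loadings, paths and intercepts transforming consistently.

**Standardized comparator.** `fit_std` refits the same structure with every
block standardized (i.e. on the correlation matrix) — the classic estimator,
which the convex model reduces to exactly when all components are declared
standardized. Its ad-hoc unstandardized weights divide each standardized
weight by the indicator's SD (`W_uni = Δ_z⁻¹ W_std`); the resulting
components keep unit variance and can leave the indicators' range, which is
the interpretability failure the convex variant removes.

## Fit indexes

- `FIT^UD = 1 − Σ o²(M'SM)_tt / Σ o²(V'SV)_tt`: share of penalty-weighted
  total variance of dependent variables explained. `FIT_M^UD` and `FIT_S^UD`
  restrict the ratio to dependent indicators (with `O_z`) and dependent
  components (with `O_γ`). Per-equation R² is the unweighted version for one
  dependent component. For all-standardized models the classic FIT (over all
  T = J + P variables, an exogenous standardized component contributing its
  full unit variance unexplained) satisfies `FIT^UD = (T/T_Y)·FIT` exactly
  in-sample; AFIT applies the `d0/d1 = NT/(NT − #free parameters)`
  adjustment.
- **GFI/SRMR** compare the sample and model-implied indicator covariance on
  the correlation metric: `GFI = 1 − SS(R − R̂)/SS(R)`, SRMR the RMS
  standardized residual over the J(J+1)/2 unique elements. The implied
  matrix (isolated in `fit_indices.implied_covariance`, so an alternative
  convention is a one-point change) assumes indicators of *different* blocks
  are uncorrelated given the component vector: cross-block entries are
  `(LΦ̂L')_jk` with `L = SW(W'SW)⁻¹` the regression map of indicators on the
  components and `Φ̂` the structurally implied component covariance
  (reduced form `(I−B')⁻¹Ω(I−B)⁻¹`, exogenous block at its sample values,
  dependent components contributing their sample structural residual
  variances, mutually uncorrelated). Within-block entries are reproduced as
  observed — the estimator treats within-block error covariances as free
  residuals — so the diagonal residual is zero and the implied matrix is
  undefined for cyclic structural graphs (an error; estimation itself
  handles cycles). Published values for this example were computed under a
  convention we could not reconstruct exactly — the loading-product implied
  matrix matches the published GFI almost perfectly but implies a ~3× larger
  SRMR than published — so these two indexes should be compared across
  software only qualitatively; under our convention the ACSI example gives
  GFI .999 and SRMR .017.

## Resampling

- **Bootstrap** (default K = 4000; scale down for exploration): resample N
  rows with replacement, refit warm-started from the full-sample weights,
  report replicate SDs as SEs and 2.5/97.5 percentiles as the 95% CI
  (percentile flavor — the field's default; no BCa). Standardized columns
  are sign-aligned to the full-sample solution before aggregation; the model
  is exactly equivariant under the flip `(w_p, C_p·, B_p·, B_·p, b0_p) →
  −(...)`, so alignment is a relabelling. Replicates that fail (e.g. a
  resample with a constant indicator) are dropped and counted; >5% drops
  warns. Convex columns need no alignment, and a single-indicator convex
  weight is structurally fixed at 1 (SE exactly 0).
- **Out-of-bag prediction error** `OPE^UD`: per replicate, fit on the
  bootstrap sample, predict the rows *not* drawn, and form the ratio of
  penalty-weighted prediction SS to mean-prediction SS (penalties and any
  standardization from the training sample); average over replicates.
  0 = perfect, 1 = no better than means. Measurement/structural variants
  restrict to dependent indicators/components. The all-standardized identity
  `OPE^UD = (T/T_Y)·OPE − (T−T_Y)/T_Y` holds exactly only in expectation
  (held-out rows are standardized with training statistics), which is why
  the test checks it stochastically at N = 500, K = 50, tolerance .02.
  **Model comparison** evaluates all candidate models on *shared* train/test
  splits: OPE differences between models are then paired, which cancels the
  common replicate noise and makes orderings between closely matched models
  (differences of order 1e-3) stable at moderate K.
- When only moments are available, `surrogate_data` draws multivariate
  normal rows matching them — clearly an approximation whose resampling
  results inherit the normality assumption.

## Synthetic populations and recovery studies

`PopulationModel` prescribes per block: indicator means, SDs and a
within-block correlation matrix; plus a component correlation level (or
matrix) and optional structural path values. The population covariance is
assembled exactly from these conditions: blocks as `D R D`; cross-block as
the minimum-Frobenius-norm matrix consistent with the prescribed component
covariance through seed weight vectors (default equal weights); with paths,
the component covariance propagates through the reduced form and the implied
structural residual variance must stay positive (else an error, as when no
PSD covariance exists at all).

Because the within-block correlation patterns are prescribed *exactly*, an
arbitrary prescribed weight vector is generally not a stationary point of
the objective at that covariance. The **population parameter values** — the
truth of a recovery study — are therefore defined as the estimator's fixed
point on the exact population moments (a tight-tolerance fit to μ, Σ), which
is the value any consistent estimator converges to and is recovered to 1e-6
when the exact moments are refitted. Seed weights only shape the cross-block
construction.

The reference population has four convex components with four indicators
each, staggered block means (6…3 down to 4.5…1.5), the moderate
within-block correlation pattern, linearly spread variances [1, 2, 3, 4] and
component correlation .2 — the middle level of each factor; all three
levels of each factor are exposed as constants. Non-normal margins use a
third-order polynomial (Fleishman) transform with a pairwise
intermediate-correlation adjustment (cubic solve per pair) so the covariance
target is preserved. The skew-1.25 condition's kurtosis target of 3.75 is
interpreted as *excess* kurtosis: the third-order polynomial's feasible
region at skewness 1.25 starts at raw kurtosis ≈ 4.34, so a raw reading of
3.75 is unattainable by this (or any Fleishman-type) transform.

`run_recovery_study` draws `reps` samples per sample size (default grid 100,
400, 1500 with 200 replicates — a deliberately scaled-down study that still
pins bias to ~1e-3), refits each, and reports `|E(θ̂) − θ|` and
`√E(θ̂ − θ)²` per parameter, averaged within families (weights, loadings,
intercepts, component means, component variances).

**What the generator does not emulate.** Margins are continuous (normal or
polynomial-transformed normal): real rating data are discrete and bounded,
binary items (like the complaint flag in the ACSI example, carried as
continuous here as in common practice) are not Bernoulli, and there are no
missing values, outliers or clustered sampling. Passing recovery tests shows
the estimator tracks its own population functional under the prescribed
moment structure — not that the model is right for any particular real
dataset.

## Numerical choices

- Covariances always use the N−1 denominator (pinned by the requirement that
  standardizing {49, 50, 51} yields {−1, 0, 1}).
- `MomentSet` accepts PSD matrices; positive-definiteness is enforced per
  convex block at fit time. Ridge fallback magnitude 1e-10 × mean diagonal.
- Active-set enumeration for non-negative weights is exact up to 2^k subsets
  per block; feasibility and multiplier tolerances are 1e-12/1e-9.
- Ties in the simplex vertex fallback break toward the lowest objective
  vertex; the deterministic update cycle (declaration order) fixes the
  iteration path.
- The bundled ACSI moments are the published two-decimal values; downstream
  estimates inherit roughly ±.01–.015 of print-rounding slack, and two
  printed correlations are internally inconsistent with the printed
  covariances by up to ~.009 (worst for pairs involving the small-variance
  binary item).

## Limitations

Higher-order, multilevel and interaction components, categorical-indicator
quantification, factor-based variants and missing-data handling are out of
scope. Analytic standard errors are not provided (bootstrap only). The
implied-covariance convention behind GFI/SRMR is one defensible choice among
several in use. Cyclic structural graphs are estimated (with a warning) but
have no implied covariance and hence no GFI/SRMR.
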