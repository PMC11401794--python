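# convexgsca

Structured component analysis with **convex components**: composite indexes
whose scores stay on their indicators' original measurement scale.

## The problem

Component-based structural models (the GSCA family) build composites
`γ = W'z` from blocks of observed indicators and estimate path relations
among them. The classic estimator standardizes everything, so a component
score only tells you where a person stands *relative to the sample* — a life
satisfaction of "0.7 SD above average" — never whether they are satisfied.
The usual fix, dividing each standardized weight by its indicator's SD,
backfires: the rescaled composite keeps unit variance, can leave the
indicators' range, and quietly hands the most influence to the *least*
variable indicator.

A **convex component** constrains each weight column to sum to one
(optionally to be non-negative). Its scores are then convex combinations of
the indicators, so scores, means and SDs are read directly on the original
scale (a depression index of 3 means "as depressed as someone rating every
symptom 3"), weights are contribution rates, and the path coefficient of a
convex predictor is the expected outcome change per unit change in all of
its indicators. Blocks on incommensurable scales can stay standardized —
both kinds coexist in one model.

## The estimator

With `V = [I_J, W]`, `A = [C, B]` (loadings, paths) and intercepts
`a0 = [c0; b0]`, parameters minimize the penalty-weighted sum of error
variances of all dependent variables

    f(W, A, a0) = E( SS( ([z; γ]' − (a0' + z'WA)) O ) ),

subject to `1'w_p = 1` (convex) or `w_p'S_p w_p = 1` (standardized) per
component. The diagonal penalty `O` divides each dependent variable's error
by its block's average SD so no block dominates by scale alone. An
alternating-least-squares algorithm cycles exact conditional solves
(regressions for `A, a0`; constrained quadratic minimization per weight
column), so the objective is monotone non-increasing; everything is computed
from means and covariances, which makes a moment table (like a published
covariance matrix) a complete input. Model quality is summarized by
FIT^UD (overall weighted explained variance) with measurement/structural
local variants, per-equation R², GFI/SRMR from a model-implied covariance,
bootstrap SEs and percentile CIs, and an out-of-bag prediction error
(OPE^UD) for comparing models by predictive generalizability.

## Worked example

The package bundles the published moment set of the American Customer
Satisfaction Index survey (14 items, N = 774) and its six-component model —
expectations (CE), perceived quality (PQ), perceived value (PV),
satisfaction (CS), complaints (CC) convex; loyalty (CL) standardized because
its two items mix a 1–10 and a 0–50 scale.

```python
from convexgsca import fit_cvx, load_acsi_fixture

moments, spec = load_acsi_fixture()
fit = fit_cvx(spec, moments)
print(fit.params.weights()["CS"].round(3))
print(fit.component_summary().round(3).loc["CS"])
print(round(fit.fit_indexes["fit_ud"], 3))
```

prints

```
indicator
z9     0.424
z10    0.253
z11    0.323
Name: weight, dtype: float64
mean    7.127
sd      2.351
Name: CS, dtype: float64
0.712
```

Read: overall satisfaction (z9) contributes 42% of the satisfaction
composite; the average customer sits at 7.1 on the 1–10 satisfaction scale
with an SD of 2.4 scale points; the model explains 71% of the weighted
variance of all dependent variables. `fit.params.paths()` gives the
structural coefficients (e.g. PQ → CS ≈ 0.72: a one-point rise on every
quality item predicts a 0.72-point rise in satisfaction).

The `examples/` scripts are short narratives, one per capability:
`fit_customer_satisfaction.py` (full fit and indexes),
`convex_vs_standardized.py` (why the ad-hoc rescaling misleads),
`bootstrap_and_model_comparison.py` (SEs, CIs, OPE comparison of nested
models), `recovery_study.py` (Monte-Carlo bias/RMSE). A thin CLI mirrors
them: `cvxgsca fit|bootstrap|ope|compare|simulate --help`.

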