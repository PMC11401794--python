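"""Alternating least squares estimation of component models.

The model couples three sub-models for indicators ``z`` (J of them) and
components ``gamma = W'z`` (P of them)::

    z     = c0 + C' gamma + xi      (measurement)
    gamma = b0 + B' gamma + zeta    (structural)

Stacking ``u = [z; gamma] = V'z`` with ``V = [I_J, W]``, ``A = [C, B]`` and
``a0 = [c0; b0]``, the estimator minimizes the penalty-weighted sum of error
variances of all dependent variables

    f(W, A, a0) = E( SS( (u' - (a0' + z' W A)) O ) ),

subject to, per component, either the convex constraint ``1'w_p = 1``
(optionally ``w_p >= 0``) or the unit-variance constraint
``w_p' S_p w_p = 1``.  ``O`` is the diagonal penalty of
:func:`convexgsca.moments_io.build_penalty_matrix`.

Everything is evaluated from first and second moments: writing
``M = V - W A``, the optimal intercepts are ``a0 = M' mu`` and

    f = sum_t o_t^2 [ ((M' mu - a0)_t)^2 + (M' S M)_tt ].

The expectation convention means the raw-data sum of squares equals
``(N - 1) f`` once intercepts absorb the means.

The alternating scheme cycles two exact minimizations — (i) all free
loadings, paths and intercepts, one regression equation at a time, and
(ii) one weight column at a time under its constraint — so the objective is
non-increasing at every step and the trace is monotone by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model_spec import CONVEX, STANDARDIZED, ModelSpec, validate_spec
from .moments_io import MomentSet, PenaltyMatrix, build_penalty_matrix, moments_from_data

__all__ = [
    "ParameterSet",
    "FitResult",
    "prepare_moments",
    "objective_value",
    "update_structural_params",
    "update_weight_vector",
    "fit_cvx",
    "fit_std",
    "rescale_weights_unstandardized",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Estimated weights, loadings, paths and intercepts.

    ``W`` is J x P, ``C`` is P x J, ``B`` is P x P and ``a0`` stacks the
    measurement intercepts ``c0`` (J) over the structural intercepts ``b0``
    (P).  ``constraint_status`` records, per component, whether its weight
    column is sum-to-one, unit-variance or fixed.
    """

    spec: ModelSpec
    W: np.ndarray
    C: np.ndarray
    B: np.ndarray
    a0: np.ndarray
    constraint_status: dict[str, str] = field(default_factory=dict)

    @property
    def A(self) -> np.ndarray:
        """P x (J + P) matrix [C, B]."""
        return np.hstack([self.C, self.B])

    @property
    def c0(self) -> np.ndarray:
        return self.a0[: self.spec.J]

    @property
    def b0(self) -> np.ndarray:
        return self.a0[self.spec.J:]

    def weights(self) -> pd.Series:
        idx, vals = [], []
        for p, comp in enumerate(self.spec.component_names):
            for j in self.spec.block_indices(comp):
                idx.append((comp, self.spec.indicator_names[j]))
                vals.append(self.W[j, p])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["component", "indicator"]), name="weight")

    def loadings(self) -> pd.Series:
        idx, vals = [], []
        for p, comp in enumerate(self.spec.component_names):
            for j in self.spec.block_indices(comp):
                idx.append((comp, self.spec.indicator_names[j]))
                vals.append(self.C[p, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["component", "indicator"]), name="loading")

    def paths(self) -> pd.Series:
        names = self.spec.component_names
        idx = [(a, b) for a, b in self.spec.structural_edges]
        vals = [self.B[names.index(a), names.index(b)] for a, b in idx]
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["predictor", "outcome"]), name="path")

    def flat(self) -> pd.Series:
        """All free parameters as one labelled vector (for bootstrapping)."""
        idx: list[tuple] = []
        vals: list[float] = []
        for fam, series in (("weight", self.weights()), ("loading", self.loadings()), ("path", self.paths())):
            for key, v in series.items():
                idx.append((fam, *key))
                vals.append(v)
        for name, v in zip(self.spec.indicator_names, self.c0):
            idx.append(("c0", name, ""))
            vals.append(v)
        for name, v in zip(self.spec.component_names, self.b0):
            idx.append(("b0", name, ""))
            vals.append(v)
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["family", "a", "b"]))


@dataclass
class FitResult:
    """A converged (or max-iteration) ALS solution plus diagnostics."""

    params: ParameterSet
    moments: MomentSet            # on the fitting metric (std blocks standardized)
    penalty: PenaltyMatrix
    objective_trace: list[float]
    converged: bool
    n_iter: int
    residual_variances: np.ndarray   # per variable t (zero-penalty entries included)
    component_means: np.ndarray
    component_sds: np.ndarray
    fit_indexes: dict = field(default_factory=dict)
    kind: str = "cvx"

    @property
    def spec(self) -> ModelSpec:
        return self.params.spec

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def component_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.component_means, "sd": self.component_sds},
            index=self.spec.component_names,
        )


# ---------------------------------------------------------------------------
# Moment preparation
# ---------------------------------------------------------------------------

def prepare_moments(spec: ModelSpec, moments: MomentSet) -> MomentSet:
    """Reorder to the spec's indicator order and standardize the indicators
    of standardized blocks (their means become 0, variances 1, and their
    covariances with other indicators are rescaled accordingly)."""
    moments = moments.reorder(spec.indicator_names)
    scale = np.ones(spec.J)
    mu = moments.mu.copy()
    for comp in spec.component_names:
        if spec.scale_of(comp) == STANDARDIZED:
            idx = spec.block_indices(comp)
            sd = moments.sd[idx]
            if np.any(sd <= 0):
                raise ValueError(f"zero-variance indicator in block {comp!r}")
            scale[idx] = 1.0 / sd
            mu[idx] = 0.0
    S = moments.S * np.outer(scale, scale)
    return MomentSet(moments.names, mu, S, moments.N)


def _check_convex_blocks(spec: ModelSpec, prep: MomentSet) -> None:
    # linear independence of each multi-indicator convex block (the
    # uniqueness premise); degenerate blocks are rejected, not regularized
    for comp in spec.component_names:
        idx = spec.block_indices(comp)
        if spec.scale_of(comp) == CONVEX and len(idx) > 1:
            Sb = prep.S[np.ix_(idx, idx)]
            ev = np.linalg.eigvalsh(Sb)
            if ev.min() <= 1e-10 * max(ev.max(), 1.0):
                raise ValueError(
                    f"indicators of convex block {comp!r} are linearly dependent; "
                    "convex weights would not be identified"
                )


# ---------------------------------------------------------------------------
# Exact conditional updates
# ---------------------------------------------------------------------------

def _solve_psd(G: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        sol = np.linalg.solve(G, rhs)
        if np.all(np.isfinite(sol)):
            return sol
    except np.linalg.LinAlgError:
        pass
    warnings.warn("singular normal equations; ridge fallback", UserWarning, stacklevel=3)
    ridge = 1e-10 * max(np.trace(np.atleast_2d(G)) / max(G.shape[0], 1), 1e-30)
    return np.linalg.solve(G + ridge * np.eye(G.shape[0]), rhs)


def _free_predictors(spec: ModelSpec):
    """Per variable t = 0..T-1, indices of components with a free coefficient."""
    owner = np.zeros(spec.J, dtype=int)
    for p, comp in enumerate(spec.component_names):
        owner[spec.block_indices(comp)] = p
    bpat = spec.b_pattern()
    preds = [[owner[j]] for j in range(spec.J)]
    preds += [list(np.flatnonzero(bpat[:, q])) for q in range(spec.P)]
    return preds


def update_structural_params(W: np.ndarray, moments: MomentSet, O: PenaltyMatrix, spec: ModelSpec):
    """Exact least-squares update of ``A = [C, B]`` and intercepts for fixed W.

    The penalty is diagonal, so each dependent variable's equation separates
    and its penalty entry scales the residual without moving the minimizer:
    each free coefficient vector solves the regression of its variable on
    its predictor components, and the intercepts satisfy the mean equation
    ``a0 = E([z; gamma]) - A' W' mu``.
    """
    J, P = spec.J, spec.P
    S, mu = moments.S, moments.mu
    G = W.T @ S @ W
    H = W.T @ S               # cov(gamma, z)
    A = np.zeros((P, J + P))
    for t, F in enumerate(_free_predictors(spec)):
        if not F:
            continue
        rhs = H[F, t] if t < J else G[np.ix_(F, [t - J])].ravel()
        A[F, t] = _solve_psd(G[np.ix_(F, F)], rhs)
    gbar = W.T @ mu
    a0 = np.concatenate([mu, gbar]) - A.T @ gbar
    return A, a0


def _residual_matrix(W: np.ndarray, A: np.ndarray, J: int) -> np.ndarray:
    """M = V - W A with V = [I_J, W]; residual u - prediction is M'z - a0."""
    V = np.hstack([np.eye(J), W])
    return V - W @ A


def _weighted_resvar(M: np.ndarray, S: np.ndarray) -> np.ndarray:
    return np.einsum("jt,jk,kt->t", M, S, M, optimize=True)


def objective_value(params: ParameterSet, moments: MomentSet, O: PenaltyMatrix) -> float:
    """Evaluate the penalized objective for arbitrary (not necessarily
    optimal) intercepts, purely from moments."""
    spec = params.spec
    moments = moments.reorder(spec.indicator_names)
    M = _residual_matrix(params.W, params.A, spec.J)
    o2 = O.o ** 2
    mean_gap = M.T @ moments.mu - params.a0
    return float(np.sum(o2 * (_weighted_resvar(M, moments.S) + mean_gap ** 2)))


def _simplex_ls(Sbb: np.ndarray, c: np.ndarray, quad: float, nonneg: bool) -> np.ndarray:
    """Minimize quad * w'Sbb w + 2 c'w subject to 1'w = 1 (and w >= 0).

    The equality-constrained problem is a single KKT solve.  With the
    non-negativity constraint the exact solution is found by enumerating
    active sets (block sizes are small), checking primal feasibility and the
    sign of the multipliers.
    """
    k = len(c)
    ones = np.ones(k)

    def eq_solve(idx):
        m = len(idx)
        K = np.zeros((m + 1, m + 1))
        K[:m, :m] = 2.0 * quad * Sbb[np.ix_(idx, idx)]
        K[:m, m] = 1.0
        K[m, :m] = 1.0
        rhs = np.concatenate([-2.0 * c[idx], [1.0]])
        sol = _solve_psd(K, rhs)
        return sol[:m], sol[m]

    w_eq, _ = eq_solve(list(range(k)))
    if not nonneg:
        return w_eq
    if np.all(w_eq >= -1e-12):
        return np.clip(w_eq, 0.0, None) / max(np.clip(w_eq, 0.0, None).sum(), 1e-300)

    best, best_f = None, np.inf
    for m in range(k, 0, -1):
        for idx in combinations(range(k), m):
            idx = list(idx)
            w_sub, lam = eq_solve(idx)
            if np.any(w_sub < -1e-12):
                continue
            w = np.zeros(k)
            w[idx] = np.clip(w_sub, 0.0, None)
            # KKT: zeroed coordinates need gradient_j + lambda >= 0
            grad = 2.0 * quad * (Sbb @ w) + 2.0 * c
            zeros = [j for j in range(k) if j not in idx]
            if zeros and np.any(grad[zeros] + lam < -1e-9 * max(abs(lam), 1.0)):
                continue
            f = quad * w @ Sbb @ w + 2.0 * c @ w
            if f < best_f:
                best, best_f = w, f
    if best is None:  # numerically degenerate; fall back to a vertex
        j = int(np.argmin(np.diag(Sbb) * quad + 2.0 * c))
        best = np.zeros(k)
        best[j] = 1.0
    return best


def update_weight_vector(
    p: int,
    W: np.ndarray,
    A: np.ndarray,
    moments: MomentSet,
    O: PenaltyMatrix,
    spec: ModelSpec,
    M: np.ndarray | None = None,
) -> np.ndarray:
    """Exact minimizer of the objective over one weight column.

    With every other parameter fixed, the objective is a quadratic in
    ``w_p``: writing ``beta_p = e_{J+p} - A[p, :]`` and ``M_(-p)`` for the
    residual matrix with column p's contribution removed,

        f(w) = quad * w' S_bb w + 2 c'w + const,
        quad = sum_t o_t^2 beta_t^2,   c = (S M_(-p) (o^2 * beta))_block.

    Sum-to-one columns solve the single-equality KKT system; unit-variance
    columns minimize the linear term on the ellipsoid ``w' S_bb w = 1``
    (equivalently, the unconstrained solve renormalized); the optional
    non-negative case is an exact active-set search over the simplex.
    """
    J = spec.J
    comp = spec.component_names[p]
    idx = spec.block_indices(comp)
    if spec.is_weight_fixed(comp):
        return np.ones(1)
    if M is None:
        M = _residual_matrix(W, A, J)
    beta = -A[p, :].copy()
    beta[J + p] += 1.0
    o2 = O.o ** 2
    M_minus = M - np.outer(W[:, p], beta)
    quad = float(np.sum(o2 * beta ** 2))
    c = (moments.S @ (M_minus @ (o2 * beta)))[idx]
    Sbb = moments.S[np.ix_(idx, idx)]

    if spec.scale_of(comp) == CONVEX:
        return _simplex_ls(Sbb, c, quad, spec.nonneg_weights)
    # standardized: min c'w on the ellipsoid w'Sbb w = 1
    if np.allclose(c, 0.0) or quad == 0.0:
        w = W[idx, p]
    else:
        w = -_solve_psd(Sbb, c)
    nrm = float(w @ Sbb @ w)
    if nrm <= 0:
        w = np.ones(len(idx))
        nrm = float(w @ Sbb @ w)
    return w / np.sqrt(nrm)


# ---------------------------------------------------------------------------
# Full fits
# ---------------------------------------------------------------------------

def _initial_weights(spec: ModelSpec, prep: MomentSet, init: str, rng) -> np.ndarray:
    W = np.zeros((spec.J, spec.P))
    for p, comp in enumerate(spec.component_names):
        idx = spec.block_indices(comp)
        k = len(idx)
        if init == "equal":
            w = np.full(k, 1.0 / k)
        elif init == "random":
            if spec.scale_of(comp) == CONVEX:
                w = rng.dirichlet(np.ones(k))
            else:
                w = rng.standard_normal(k)
        else:
            raise ValueError(f"unknown init {init!r}")
        if spec.scale_of(comp) == STANDARDIZED:
            Sb = prep.S[np.ix_(idx, idx)]
            w = w / np.sqrt(max(w @ Sb @ w, 1e-300))
        W[idx, p] = w
    return W


def _als(spec, prep, O, W, tol, max_iter):
    A, a0 = update_structural_params(W, prep, O, spec)
    M = _residual_matrix(W, A, spec.J)
    o2 = O.o ** 2
    trace = [float(np.sum(o2 * _weighted_resvar(M, prep.S)))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for p, comp in enumerate(spec.component_names):
            if spec.is_weight_fixed(comp):
                continue
            idx = spec.block_indices(comp)
            beta = -A[p, :].copy()
            beta[spec.J + p] += 1.0
            M_minus = M - np.outer(W[:, p], beta)
            w_new = update_weight_vector(p, W, A, prep, O, spec, M=M)
            W[idx, p] = w_new
            wcol = np.zeros(spec.J)
            wcol[idx] = w_new
            W[:, p] = wcol
            M = M_minus + np.outer(wcol, beta)
        A, a0 = update_structural_params(W, prep, O, spec)
        M = _residual_matrix(W, A, spec.J)
        f = float(np.sum(o2 * _weighted_resvar(M, prep.S)))
        trace.append(f)
        if abs(trace[-2] - f) < tol:
            converged = True
            break
    return W, A, a0, trace, converged, it


def _as_moments(data) -> MomentSet:
    if isinstance(data, MomentSet):
        return data
    return moments_from_data(data)


def fit_cvx(
    spec: ModelSpec,
    data,
    init: str = "equal",
    tol: float = 1e-5,
    max_iter: int = 1000,
    n_starts: int = 1,
    seed: int | None = None,
    warm_start: np.ndarray | None = None,
    compute_indexes: bool = True,
) -> FitResult:
    """Fit the convex component model by alternating least squares.

    ``data`` is either a raw N x J table or a :class:`MomentSet` (both give
    identical estimates: moments are sufficient).  The default equal-weight
    start is deterministic; ``n_starts > 1`` adds random restarts (Dirichlet
    on the simplex for convex blocks, normalized Gaussian for standardized
    ones) and the best objective wins.  ``warm_start`` supplies a full J x P
    weight matrix, used by the bootstrap to stabilize replicates.

    Non-convergence at ``max_iter`` flags the result instead of raising.
    """
    spec = spec if spec._validated else validate_spec(spec)
    moments = _as_moments(data)
    prep = prepare_moments(spec, moments)
    _check_convex_blocks(spec, prep)
    O = build_penalty_matrix(spec, prep)
    rng = np.random.default_rng(seed)

    best = None
    starts: list[np.ndarray] = []
    if warm_start is not None:
        starts.append(np.array(warm_start, dtype=float))
    else:
        starts.append(_initial_weights(spec, prep, "equal" if init == "equal" else "random", rng))
    for _ in range(n_starts - 1):
        starts.append(_initial_weights(spec, prep, "random", rng))
    for W0 in starts:
        W, A, a0, trace, conv, it = _als(spec, prep, O, W0.copy(), tol, max_iter)
        if best is None or trace[-1] < best[3][-1]:
            best = (W, A, a0, trace, conv, it)
    W, A, a0, trace, conv, it = best

    status = {}
    for comp in spec.component_names:
        if spec.is_weight_fixed(comp):
            status[comp] = "fixed"
        elif spec.scale_of(comp) == CONVEX:
            status[comp] = "sum-to-one"
        else:
            status[comp] = "unit-variance"
    params = ParameterSet(spec, W, A[:, : spec.J], A[:, spec.J:], a0, status)
    M = _residual_matrix(W, A, spec.J)
    resvar = _weighted_resvar(M, prep.S)
    G = W.T @ prep.S @ W
    result = FitResult(
        params=params,
        moments=prep,
        penalty=O,
        objective_trace=trace,
        converged=conv,
        n_iter=it,
        residual_variances=resvar,
        component_means=W.T @ prep.mu,
        component_sds=np.sqrt(np.clip(np.diag(G), 0.0, None)),
    )
    if not conv:
        warnings.warn(f"ALS did not converge in {max_iter} iterations", UserWarning, stacklevel=2)
    if compute_indexes:
        from . import fit_indices
        result.fit_indexes = fit_indices.fit_index_set(result)
    return result


def fit_std(
    spec: ModelSpec,
    data,
    init: str = "equal",
    tol: float = 1e-5,
    max_iter: int = 1000,
    n_starts: int = 1,
    seed: int | None = None,
    warm_start: np.ndarray | None = None,
    compute_indexes: bool = True,
) -> FitResult:
    """Classic standardized fit: every component unit-variance, every
    indicator standardized, i.e. the model is fitted to the correlation
    matrix.  Convex scale declarations in ``spec`` are overridden."""
    std_spec = validate_spec(
        ModelSpec(
            blocks={c: list(b) for c, b in spec.blocks.items()},
            scale_type={c: STANDARDIZED for c in spec.component_names},
            structural_edges=list(spec.structural_edges),
            nonneg_weights=False,
        )
    )
    res = fit_cvx(std_spec, data, init=init, tol=tol, max_iter=max_iter,
                  n_starts=n_starts, seed=seed, warm_start=warm_start,
                  compute_indexes=compute_indexes)
    res.kind = "std"
    return res


def rescale_weights_unstandardized(fit: FitResult, moments) -> tuple[np.ndarray, np.ndarray]:
    """Ad-hoc unstandardized weights from a standardized fit.

    Each standardized weight is divided by its indicator's sample SD
    (``W_uni = Delta_z^{-1} W_std``); the implied unstandardized component
    score means are ``mu' W_uni``.  The resulting components keep unit
    variance, which is exactly the interpretability problem convex
    components avoid.
    """
    if fit.kind != "std":
        raise ValueError("expects a standardized fit")
    moments = _as_moments(moments).reorder(fit.spec.indicator_names)
    sd = moments.sd
    if np.any(sd <= 0):
        raise ValueError("zero-variance indicator")
    W_uni = fit.params.W / sd[:, None]
    return W_uni, moments.mu @ W_uni
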