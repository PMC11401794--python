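"""Bootstrap inference and out-of-bag cross-validation.

Standard errors and percentile confidence intervals come from refitting the
model on bootstrap resamples of the raw rows (warm-started from the
full-sample solution to stabilize the replicates).  Standardized-component
weight columns are only identified up to sign, so each replicate's columns
are sign-aligned to the full-sample solution before aggregation; the model
is exactly equivariant under such flips, so the alignment is a relabelling,
not a perturbation.  Convex columns need no alignment (the sum-to-one
constraint fixes the sign).

Predictive generalizability is measured by the out-of-bag prediction error
OPE^UD: for each bootstrap sample, the model fitted to it predicts the rows
*not* drawn into it, and the penalty-weighted prediction sum of squares is
compared with that of mean-only prediction.  0 means perfect prediction of
every dependent variable; values above 1 are worse than predicting means.
Local variants restrict the ratio to dependent indicators (measurement
model) or dependent components (structural model).  Models are compared on
*shared* train/test splits, so OPE differences between nested models are
paired and far less noisy than the index itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .als_estimation import FitResult, fit_cvx, fit_std
from .model_spec import STANDARDIZED, ModelSpec, validate_spec
from .moments_io import MomentSet, moments_from_data

__all__ = [
    "BootstrapResult",
    "OPEResult",
    "bootstrap_estimates",
    "ope_ud",
    "ope_std",
    "compare_models",
    "surrogate_data",
]


def _as_rows(data, names) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[list(names)].to_numpy(dtype=float)
    X = np.asarray(data, dtype=float)
    if X.shape[1] != len(names):
        raise ValueError("column count does not match the model's indicators")
    return X


def surrogate_data(moments: MomentSet, N: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Multivariate-normal rows matching a moment set.

    A stand-in for unavailable raw data (e.g. when only printed moments are
    published); resampling results on it are approximations whose quality
    depends on how normal the real data were.
    """
    rng = np.random.default_rng(seed)
    N = N or moments.N
    X = rng.multivariate_normal(moments.mu, moments.S, size=N, method="eigh")
    return pd.DataFrame(X, columns=list(moments.names))


def _sign_align(fit: FitResult, W_ref: np.ndarray) -> FitResult:
    """Flip standardized weight columns toward a reference solution.

    Flipping component p maps (w_p, C[p,:], B[p,:], B[:,p], b0[p]) to their
    negatives; the model and objective are invariant, so this only picks one
    of two equivalent solutions.
    """
    spec = fit.spec
    s = np.ones(spec.P)
    for p, comp in enumerate(spec.component_names):
        if spec.scale_of(comp) == STANDARDIZED and fit.params.W[:, p] @ W_ref[:, p] < 0:
            s[p] = -1.0
    if np.all(s == 1.0):
        return fit
    Ds = np.diag(s)
    pr = fit.params
    pr.W = pr.W @ Ds
    pr.C = Ds @ pr.C
    pr.B = Ds @ pr.B @ Ds
    pr.a0 = np.concatenate([pr.c0, s * pr.b0])
    fit.component_means = s * fit.component_means
    return fit


@dataclass
class BootstrapResult:
    """Replicate summary: SEs, percentile CIs, raw replicate estimates."""

    K: int
    estimate: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    replicates: pd.DataFrame
    n_failed: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimate, "se": self.se,
             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}
        )


def bootstrap_estimates(
    data,
    spec: ModelSpec,
    K: int = 4000,
    seed: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 1000,
    standardized: bool = False,
) -> BootstrapResult:
    """Bootstrap SEs and 95 percent percentile CIs for all free parameters.

    Rows are resampled with replacement; each replicate is refitted from the
    full-sample weights.  Replicates whose fit fails (e.g. a resample with a
    constant indicator) are dropped and counted; more than 5 percent drops
    triggers a warning.
    """
    spec = spec if spec._validated else validate_spec(spec)
    X = _as_rows(data, spec.indicator_names)
    N = X.shape[0]
    fitter = fit_std if standardized else fit_cvx
    base = fitter(spec, moments_from_data(X), tol=tol, max_iter=max_iter, compute_indexes=False)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(K):
        idx = rng.integers(0, N, N)
        try:
            mom_k = moments_from_data(X[idx])
            fit_k = fitter(spec, mom_k, tol=tol, max_iter=max_iter,
                           warm_start=base.params.W, compute_indexes=False)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        fit_k = _sign_align(fit_k, base.params.W)
        rows.append(fit_k.params.flat())
    if n_failed > 0.05 * K:
        import warnings

        warnings.warn(f"{n_failed}/{K} bootstrap replicates failed", UserWarning, stacklevel=2)
    reps = pd.DataFrame(rows)
    est = base.params.flat()
    se = reps.std(ddof=1)
    lo = reps.quantile(0.025)
    hi = reps.quantile(0.975)
    return BootstrapResult(K, est, se, lo, hi, reps, n_failed)


# ---------------------------------------------------------------------------
# Out-of-bag prediction error
# ---------------------------------------------------------------------------

@dataclass
class OPEResult:
    ope_ud: float
    ope_m_ud: float
    ope_s_ud: float | None
    K: int
    n_dropped: int
    per_replicate: np.ndarray  # (K_eff, 3) ratios; structural column NaN if absent


def _prepare_test(X: np.ndarray, spec: ModelSpec, train_mu: np.ndarray, train_sd: np.ndarray) -> np.ndarray:
    """Put held-out rows on the training sample's fitting metric."""
    Xt = X.copy()
    for comp in spec.component_names:
        if spec.scale_of(comp) == STANDARDIZED:
            idx = spec.block_indices(comp)
            Xt[:, idx] = (Xt[:, idx] - train_mu[idx]) / train_sd[idx]
    return Xt


def _oob_ratios(fit_k: FitResult, Xt: np.ndarray, classic: bool = False):
    """(overall, measurement, structural) weighted PRESS ratios on one test set.

    ``classic`` evaluates every variable with unit penalty (the standardized
    OPE); otherwise only dependent variables enter, weighted by the penalty.
    """
    spec = fit_k.spec
    J = spec.J
    W, A, a0 = fit_k.params.W, fit_k.params.A, fit_k.params.a0
    Gm = Xt @ W
    U = np.hstack([Xt, Gm])
    pred = a0[None, :] + Gm @ A
    mu = fit_k.moments.mu
    null = np.concatenate([mu, W.T @ mu])
    o = np.ones(J + spec.P) if classic else fit_k.penalty.o
    R2 = ((U - pred) * o) ** 2
    N2 = ((U - null[None, :]) * o) ** 2
    overall = R2.sum() / N2.sum()
    meas = R2[:, :J].sum() / N2[:, :J].sum()
    if classic or not np.any(o[J:] > 0):
        struct = np.nan if not classic else R2[:, J:].sum() / max(N2[:, J:].sum(), 1e-300)
    else:
        struct = R2[:, J:].sum() / N2[:, J:].sum()
    return overall, meas, struct


def _ope_engine(X: np.ndarray, specs: list[ModelSpec], K: int, seed, tol, max_iter, classic: bool):
    """Shared-split OPE for one or more model specifications."""
    N = X.shape[0]
    fitter = fit_std if classic else fit_cvx
    bases = [fitter(sp, moments_from_data(X), tol=tol, max_iter=max_iter, compute_indexes=False)
             for sp in specs]
    rng = np.random.default_rng(seed)
    ratios = [[] for _ in specs]
    dropped = 0
    for _ in range(K):
        idx = rng.integers(0, N, N)
        oob = np.setdiff1d(np.arange(N), idx)
        if oob.size == 0:
            dropped += 1
            continue
        try:
            mom_k = moments_from_data(X[idx])
        except ValueError:
            dropped += 1
            continue
        ok = True
        reps = []
        for sp, base in zip(specs, bases):
            try:
                fit_k = fitter(sp, mom_k, tol=tol, max_iter=max_iter,
                               warm_start=base.params.W, compute_indexes=False)
            except (ValueError, np.linalg.LinAlgError):
                ok = False
                break
            raw_mu = X[idx].mean(axis=0)
            raw_sd = X[idx].std(axis=0, ddof=1)
            if classic:
                sd_all = np.where(raw_sd > 0, raw_sd, 1.0)
                Xt = (X[oob] - raw_mu) / sd_all
            else:
                Xt = _prepare_test(X[oob], sp, raw_mu, raw_sd)
            reps.append(_oob_ratios(fit_k, Xt, classic=classic))
        if not ok:
            dropped += 1
            continue
        for lst, r in zip(ratios, reps):
            lst.append(r)
    return [np.array(r) for r in ratios], dropped


def ope_ud(data, spec: ModelSpec, K: int = 100, seed: int | None = None,
           tol: float = 1e-5, max_iter: int = 1000) -> OPEResult:
    """Out-of-bag prediction error (overall, measurement, structural)."""
    spec = spec if spec._validated else validate_spec(spec)
    X = _as_rows(data, spec.indicator_names)
    (arr,), dropped = _ope_engine(X, [spec], K, seed, tol, max_iter, classic=False)
    struct = float(np.nanmean(arr[:, 2])) if not np.all(np.isnan(arr[:, 2])) else None
    return OPEResult(float(arr[:, 0].mean()), float(arr[:, 1].mean()), struct,
                     K, dropped, arr)


def ope_std(data, spec: ModelSpec, K: int = 100, seed: int | None = None,
            tol: float = 1e-5, max_iter: int = 1000) -> float:
    """Classic OPE of the standardized model: every variable (exogenous
    components included) enters with unit penalty, data standardized on the
    training sample's statistics."""
    spec = spec if spec._validated else validate_spec(spec)
    X = _as_rows(data, spec.indicator_names)
    (arr,), _ = _ope_engine(X, [spec], K, seed, tol, max_iter, classic=True)
    return float(arr[:, 0].mean())


def compare_models(data, specs: dict[str, ModelSpec], K: int = 100,
                   seed: int | None = None, tol: float = 1e-5,
                   max_iter: int = 1000) -> pd.DataFrame:
    """OPE^UD of several models on shared bootstrap splits (paired)."""
    names = list(specs)
    sps = [specs[n] if specs[n]._validated else validate_spec(specs[n]) for n in names]
    X = _as_rows(data, sps[0].indicator_names)
    arrs, dropped = _ope_engine(X, sps, K, seed, tol, max_iter, classic=False)
    out = pd.DataFrame(
        {
            "ope_ud": [a[:, 0].mean() for a in arrs],
            "ope_m_ud": [a[:, 1].mean() for a in arrs],
            "ope_s_ud": [np.nanmean(a[:, 2]) for a in arrs],
        },
        index=names,
    )
    out.attrs["n_dropped"] = dropped
    return out
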