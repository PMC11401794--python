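"""Goodness-of-fit indexes for fitted component models.

Three families are provided:

* **FIT^UD and its local variants** — one minus the ratio of penalty-weighted
  residual variance to penalty-weighted total variance, over all dependent
  variables (FIT^UD), over dependent indicators only (FIT_M^UD, measurement
  model) and over dependent components only (FIT_S^UD, structural model).
  When every variable is standardized, FIT^UD = (T / T_Y) * FIT, with
  T = P + J and T_Y the number of dependent variables.
* **Per-equation R²** for each dependent component (unweighted).
* **GFI and SRMR** — discrepancy between the sample and the model-implied
  indicator covariance, both compared on the correlation metric.

All ratios are formed from moments; centering is implicit because the fitted
intercepts absorb the means, so every numerator/denominator is a variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .als_estimation import FitResult, _residual_matrix, _weighted_resvar

__all__ = [
    "fit_ud",
    "local_fits",
    "r_squared",
    "gfi_srmr",
    "classic_fit",
    "fit_index_set",
    "implied_covariance",
    "implied_component_covariance",
    "gfi_srmr_matrices",
]


def _pieces(fit: FitResult):
    spec = fit.spec
    S = fit.moments.S
    W = fit.params.W
    resvar = fit.residual_variances            # per variable t
    total = np.concatenate([np.diag(S), np.diag(W.T @ S @ W)])
    return spec, resvar, total


def fit_ud(fit: FitResult) -> float:
    """Proportion of penalty-weighted total variance of all dependent
    variables explained by the model."""
    _, resvar, total = _pieces(fit)
    o2 = fit.penalty.o ** 2
    den = float(np.sum(o2 * total))
    if den <= 0:
        raise ZeroDivisionError("all dependent variables are constant")
    return 1.0 - float(np.sum(o2 * resvar)) / den


def local_fits(fit: FitResult) -> tuple[float, float | None]:
    """(FIT_M^UD, FIT_S^UD): measurement- and structural-model local fit.

    FIT_S^UD is None when the model has no dependent component.
    """
    spec, resvar, total = _pieces(fit)
    J = spec.J
    oz2 = fit.penalty.o_z ** 2
    og2 = fit.penalty.o_gamma ** 2
    fit_m = 1.0 - float(np.sum(oz2 * resvar[:J])) / float(np.sum(oz2 * total[:J]))
    if not np.any(og2 > 0):
        return fit_m, None
    fit_s = 1.0 - float(np.sum(og2 * resvar[J:])) / float(np.sum(og2 * total[J:]))
    return fit_m, fit_s


def r_squared(fit: FitResult) -> pd.Series:
    """Per dependent component, 1 - residual/total variance (unweighted)."""
    spec, resvar, total = _pieces(fit)
    dep = fit.spec.dependency_mask().dependent_components
    J = spec.J
    out = {}
    for comp in dep:
        p = spec.component_index(comp)
        out[comp] = 1.0 - resvar[J + p] / total[J + p]
    return pd.Series(out, name="r_squared")


def classic_fit(fit: FitResult) -> tuple[float, float]:
    """Classic (FIT, AFIT) for an all-standardized model.

    FIT averages explained variance over *all* T variables (an exogenous
    standardized component contributes its full unit variance unexplained).
    AFIT = 1 - (1 - FIT) d0/d1 with d0 = N*T and d1 = N*T minus the number
    of free parameters.
    """
    spec, resvar, total = _pieces(fit)
    if any(spec.scale_of(c) != "standardized" for c in spec.component_names):
        raise ValueError("classic FIT is defined for all-standardized models")
    fit_val = 1.0 - float(resvar.sum()) / float(total.sum())
    npar = int(spec.w_pattern().sum() + spec.c_pattern().sum() + spec.b_pattern().sum())
    T = spec.J + spec.P
    d0 = fit.moments.N * T
    d1 = d0 - npar
    afit = 1.0 - (1.0 - fit_val) * d0 / d1
    return fit_val, afit


# ---------------------------------------------------------------------------
# Implied covariance, GFI, SRMR
# ---------------------------------------------------------------------------

def implied_component_covariance(fit: FitResult) -> np.ndarray:
    """Structurally implied P x P component covariance.

    For a recursive structural model the reduced form is
    ``gamma = (I - B')^{-1} (b0 + zeta*)`` where the "input" vector stacks
    exogenous components (their sample covariance is taken as given) and the
    structural errors of dependent components (sample residual variances,
    mutually uncorrelated and uncorrelated with the exogenous components).
    """
    spec = fit.spec
    if spec.has_cycle():
        raise ValueError("implied covariance is undefined for a cyclic structural model")
    J, P = spec.J, spec.P
    S = fit.moments.S
    W, B = fit.params.W, fit.params.B
    G = W.T @ S @ W
    dep = {spec.component_index(c) for c in fit.spec.dependency_mask().dependent_components}
    Omega = np.zeros((P, P))
    exo = [p for p in range(P) if p not in dep]
    for p in exo:
        for q in exo:
            Omega[p, q] = G[p, q]
    for p in dep:
        Omega[p, p] = fit.residual_variances[J + p]
    IB = np.linalg.inv(np.eye(P) - B.T)
    return IB @ Omega @ IB.T


def implied_covariance(fit: FitResult) -> np.ndarray:
    """Model-implied indicator covariance on the fitting metric.

    Convention (isolated here so an alternative is a one-point change):
    indicators of *different* blocks are uncorrelated given the component
    vector, so every cross-block covariance is carried by the components —
    ``Sigma_hat[j, k] = (L Phi_hat L')[j, k]`` with ``L = S W (W'SW)^{-1}``
    the regression map of indicators on the components and ``Phi_hat`` the
    structurally implied component covariance.  Within-block residual
    covariances are unrestricted in this model (errors are freely correlated
    residuals), so within-block entries are reproduced as observed; in
    particular the diagonal residual is zero on the correlation scale.
    """
    spec = fit.spec
    S = fit.moments.S
    W = fit.params.W
    G = W.T @ S @ W
    Phi = implied_component_covariance(fit)
    L = S @ W @ np.linalg.inv(G)
    Sigma = L @ Phi @ L.T
    for comp in spec.component_names:
        idx = spec.block_indices(comp)
        Sigma[np.ix_(idx, idx)] = S[np.ix_(idx, idx)]
    return Sigma


def gfi_srmr_matrices(S: np.ndarray, Sigma: np.ndarray) -> tuple[float, float]:
    """GFI and SRMR between a sample and an implied covariance matrix, both
    on the correlation metric; the SRMR averages squared standardized
    residuals over the J(J+1)/2 unique elements."""
    d = np.sqrt(np.diag(S))
    Rs = S / np.outer(d, d)
    resid = Rs - Sigma / np.outer(d, d)
    gfi = 1.0 - float(np.sum(resid ** 2)) / float(np.sum(Rs ** 2))
    iu = np.triu_indices(S.shape[0])
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return gfi, srmr


def gfi_srmr(fit: FitResult) -> tuple[float, float]:
    """Covariance-discrepancy indexes of a fitted model."""
    return gfi_srmr_matrices(fit.moments.S, implied_covariance(fit))


def fit_index_set(fit: FitResult) -> dict:
    """All applicable indexes as a flat dict (attached to FitResult)."""
    out: dict = {"fit_ud": fit_ud(fit)}
    fm, fs = local_fits(fit)
    out["fit_m_ud"] = fm
    out["fit_s_ud"] = fs
    out["r_squared"] = r_squared(fit).to_dict()
    try:
        out["gfi"], out["srmr"] = gfi_srmr(fit)
    except ValueError:
        out["gfi"] = out["srmr"] = None
    if all(fit.spec.scale_of(c) == "standardized" for c in fit.spec.component_names):
        out["fit"], out["afit"] = classic_fit(fit)
    return out
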