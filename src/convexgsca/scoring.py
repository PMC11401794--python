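"""Component scores and their summary statistics.

Scores need raw rows (moments only determine means and SDs):
``scores = D_prep W`` where the columns of standardized blocks are
standardized first.  Convex component scores are convex combinations of
their indicators, so row-wise they stay inside the range of the indicator
values, the mean is a convex combination of the indicator means, and the SD
is at most the largest indicator SD; with linearly independent indicator
columns the weights producing a given score vector are unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .als_estimation import ParameterSet
from .model_spec import STANDARDIZED, ModelSpec
from .moments_io import standardize_block

__all__ = ["ComponentSummary", "compute_scores", "component_summary", "check_weight_uniqueness"]


@dataclass(frozen=True)
class ComponentSummary:
    """Mean, SD and (when raw scores are available) range of a component."""

    mean: float
    sd: float
    min: float | None
    max: float | None
    weights: np.ndarray


def _prepare_rows(data, spec: ModelSpec) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        missing = [z for z in spec.indicator_names if z not in data.columns]
        if missing:
            raise ValueError(f"data lacks indicator column(s) {missing}")
        X = data[spec.indicator_names].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != spec.J:
            raise ValueError("column count does not match the model's indicators")
        X = X.copy()
    for comp in spec.component_names:
        if spec.scale_of(comp) == STANDARDIZED:
            for j in spec.block_indices(comp):
                X[:, j] = standardize_block(X[:, j])
    return X


def compute_scores(data, params: ParameterSet, spec: ModelSpec | None = None) -> pd.DataFrame:
    """N x P component score table (standardized blocks standardized first)."""
    spec = spec or params.spec
    X = _prepare_rows(data, spec)
    return pd.DataFrame(X @ params.W, columns=spec.component_names)


def component_summary(weights, block_mu, block_S, block_scores=None) -> ComponentSummary:
    """Summary of one component from its block moments.

    mean = w'mu, sd = sqrt(w'Sw); min/max are filled in only when raw
    scores are supplied (ranges are a property of individual rows, not of
    moments).
    """
    w = np.asarray(weights, dtype=float)
    mu = np.asarray(block_mu, dtype=float)
    S = np.asarray(block_S, dtype=float)
    mean = float(w @ mu)
    sd = float(np.sqrt(max(w @ S @ w, 0.0)))
    lo = hi = None
    if block_scores is not None:
        sc = np.asarray(block_scores, dtype=float) @ w
        lo, hi = float(sc.min()), float(sc.max())
    return ComponentSummary(mean, sd, lo, hi, w)


def summary_table(data, params: ParameterSet) -> pd.DataFrame:
    """Per-component Mean / SD / Range table from raw rows."""
    spec = params.spec
    scores = compute_scores(data, params)
    return pd.DataFrame(
        {
            "mean": scores.mean(),
            "sd": scores.std(ddof=1),
            "min": scores.min(),
            "max": scores.max(),
        }
    )


def check_weight_uniqueness(scores, block_data) -> np.ndarray:
    """Recover the weights behind a convex component's score vector.

    Solves ``block_data @ w = scores``; with linearly independent columns the
    solution is unique, witnessing that two different convex weight vectors
    cannot produce the same scores.  Rank-deficient block data raises.
    """
    X = np.asarray(block_data, dtype=float)
    y = np.asarray(scores, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("block data columns are linearly dependent; weights not identified")
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    return w
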