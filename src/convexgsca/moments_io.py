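"""Moment-set ingestion, block standardization and the penalty matrix.

Estimation never needs raw rows: the ALS objective is a quadratic form in
the indicator mean vector ``mu`` and covariance matrix ``S`` (sample size
``N`` only matters for resampling and degrees-of-freedom adjustments), so a
:class:`MomentSet` is the sufficient statistic for a fit.  Raw N x J tables
are reduced with :func:`moments_from_data`; printed moment tables (like the
bundled American Customer Satisfaction Index example) are entered directly.

The penalty matrix ``O = blkdiag(O_z, O_gamma)`` is diagonal.  The entry of
a *dependent* variable equals the reciprocal of the average sample standard
deviation of its block of indicators, so that each block's prediction errors
contribute on a comparable footing to the objective no matter the block's
measurement scale; non-dependent variables get a zero entry, and
standardized blocks (sigma = 1) get entry one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_spec import CONVEX, STANDARDIZED, ModelSpec, validate_spec

__all__ = [
    "MomentSet",
    "PenaltyMatrix",
    "moments_from_data",
    "standardize_block",
    "build_penalty_matrix",
    "load_acsi_fixture",
    "acsi_model",
    "read_moments",
    "write_moments",
    "read_table",
]


@dataclass(frozen=True)
class MomentSet:
    """Indicator means, covariance (N-1 denominator) and sample size."""

    names: tuple[str, ...]
    mu: np.ndarray
    S: np.ndarray
    N: int

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "S", S)
        J = len(self.names)
        if mu.shape != (J,) or S.shape != (J, J):
            raise ValueError("mean/covariance dimensions do not match names")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        if self.N < 3:
            raise ValueError("sample size must be at least 3")
        eigmin = np.linalg.eigvalsh(S).min()
        scale = max(np.abs(np.diag(S)).max(), 1.0)
        if eigmin < -1e-10 * scale:
            raise ValueError("covariance matrix is not positive semidefinite")

    @property
    def J(self) -> int:
        return len(self.names)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.S))

    def correlation(self) -> np.ndarray:
        d = self.sd
        return self.S / np.outer(d, d)

    def reorder(self, names: list[str]) -> "MomentSet":
        """Return the moment set restricted/reordered to ``names``."""
        idx = [self.names.index(n) for n in names]
        return MomentSet(tuple(names), self.mu[idx], self.S[np.ix_(idx, idx)], self.N)


def moments_from_data(data) -> MomentSet:
    """Reduce an N x J table to its sufficient moments.

    ``data`` may be a :class:`pandas.DataFrame` (column names kept) or a
    2-D array (columns named ``z1..zJ``).  Covariances use the N-1
    denominator.  Missing cells and constant columns are rejected.
    """
    if isinstance(data, pd.DataFrame):
        names = tuple(str(c) for c in data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        names = tuple(f"z{j + 1}" for j in range(X.shape[1]))
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D table with at least 3 rows")
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    var = X.var(axis=0, ddof=1)
    if np.any(var <= 0):
        bad = [names[j] for j in np.flatnonzero(var <= 0)]
        raise ValueError(f"constant column(s): {bad}")
    return MomentSet(names, X.mean(axis=0), np.cov(X, rowvar=False, ddof=1), X.shape[0])


def standardize_block(scores) -> np.ndarray:
    """Center and scale a vector to mean 0, SD 1 (N-1 denominator)."""
    x = np.asarray(scores, dtype=float)
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class PenaltyMatrix:
    """Diagonals of O_z (length J) and O_gamma (length P)."""

    o_z: np.ndarray
    o_gamma: np.ndarray

    @property
    def o(self) -> np.ndarray:
        """Concatenated diagonal over all T = J + P variables."""
        return np.concatenate([self.o_z, self.o_gamma])


def build_penalty_matrix(spec: ModelSpec, moments: MomentSet) -> PenaltyMatrix:
    """Penalty diagonal: reciprocal block-average SD for dependent variables.

    Standardized blocks use sigma = 1 for every indicator, so their entries
    are exactly one when dependent.  ``moments`` must be on the metric the
    model is fitted on (i.e. standardized blocks already standardized); use
    :func:`convexgsca.als_estimation.prepare_moments` for that.
    """
    if not spec._validated:
        spec = validate_spec(spec)
    moments = moments.reorder(spec.indicator_names)
    sd = moments.sd
    if np.any(sd <= 0):
        raise ValueError("zero-variance indicator")
    dep = spec.dependency_mask()
    o_z = np.zeros(spec.J)
    o_g = np.zeros(spec.P)
    for p, comp in enumerate(spec.component_names):
        idx = spec.block_indices(comp)
        avg_sd = 1.0 if spec.scale_of(comp) == STANDARDIZED else float(sd[idx].mean())
        o_z[idx] = 1.0 / avg_sd  # all indicators carry estimated loadings
        if comp in dep.dependent_components:
            o_g[p] = 1.0 / avg_sd
    return PenaltyMatrix(o_z, o_g)


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def read_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited raw-data table with a header row (CSV/TSV sniffed)."""
    return pd.read_csv(path, sep=sep, engine="python")


def write_moments(moments: MomentSet, path: str) -> None:
    """Plain-text moment format: names / N / means / covariance rows."""
    with open(path, "w") as fh:
        fh.write("# names\n" + "\t".join(moments.names) + "\n")
        fh.write(f"# N\n{moments.N}\n# means\n")
        fh.write("\t".join(f"{v:.10g}" for v in moments.mu) + "\n# covariance\n")
        for row in moments.S:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_moments(path: str) -> MomentSet:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    names = tuple(lines[0].split())
    N = int(lines[1])
    mu = np.array([float(v) for v in lines[2].split()])
    S = np.array([[float(v) for v in ln.split()] for ln in lines[3:]])
    return MomentSet(names, mu, S, N)


# ---------------------------------------------------------------------------
# American Customer Satisfaction Index (ACSI) example
# ---------------------------------------------------------------------------
# Printed sample moments of the 14 ACSI survey items (N = 774 customers):
# upper-triangular covariances, variances on the diagonal, and means, all to
# two printed decimals.  z1-z11 and z13 are 10-point Likert items, z12 is a
# binary complaint-behavior flag, z14 is a price-tolerance percentage (0-50).

_ACSI_NAMES = tuple(f"z{j}" for j in range(1, 15))

_ACSI_MEANS = [7.34, 7.75, 6.67, 7.66, 7.59, 7.39, 5.96, 7.12, 7.59, 6.82,
               6.76, 0.14, 7.73, 31.82]

_ACSI_VARIANCES = [5.81, 5.38, 6.90, 5.31, 6.11, 6.93, 6.67, 6.18, 6.19,
                   6.27, 6.93, 0.12, 8.79, 241.11]

# row j holds cov(z_j, z_k) for k > j
_ACSI_UPPER = [
    [3.61, 2.71, 2.92, 2.91, 2.10, 1.96, 2.79, 3.01, 2.73, 3.23, -0.14, 2.62, 11.78],
    [2.88, 2.69, 2.92, 2.36, 1.48, 2.63, 2.79, 2.30, 2.64, -0.13, 2.05, 7.65],
    [2.03, 2.15, 2.56, 1.49, 2.18, 2.16, 1.96, 2.41, -0.12, 1.74, 7.77],
    [4.77, 3.76, 2.52, 4.15, 4.87, 4.35, 4.42, -0.32, 3.94, 16.86],
    [3.98, 2.48, 4.37, 5.23, 4.80, 5.01, -0.36, 4.29, 17.20],
    [2.46, 3.65, 3.95, 3.67, 3.75, -0.23, 3.18, 13.58],
    [3.43, 3.05, 2.88, 2.78, -0.14, 2.42, 11.31],
    [4.74, 4.42, 4.70, -0.29, 3.60, 16.60],
    [5.06, 5.09, -0.35, 4.55, 19.55],
    [4.96, -0.29, 3.98, 16.71],
    [-0.32, 4.74, 20.79],
    [-0.33, -1.55],
    [35.21],
]

# printed lower-triangular correlations (row j: corr(z_j, z_k) for k < j),
# kept for consistency checks against the covariance reconstruction
ACSI_PRINTED_CORRELATIONS = [
    [0.65],
    [0.43, 0.47],
    [0.53, 0.50, 0.33],
    [0.49, 0.51, 0.33, 0.84],
    [0.33, 0.39, 0.37, 0.62, 0.61],
    [0.31, 0.25, 0.22, 0.42, 0.39, 0.36],
    [0.47, 0.46, 0.33, 0.72, 0.71, 0.56, 0.53],
    [0.50, 0.48, 0.33, 0.85, 0.85, 0.60, 0.47, 0.77],
    [0.45, 0.40, 0.30, 0.75, 0.78, 0.56, 0.44, 0.71, 0.81],
    [0.51, 0.43, 0.35, 0.73, 0.77, 0.54, 0.41, 0.72, 0.78, 0.75],
    [-0.17, -0.17, -0.13, -0.40, -0.42, -0.25, -0.16, -0.34, -0.41, -0.34, -0.36],
    [0.37, 0.30, 0.22, 0.58, 0.58, 0.41, 0.32, 0.49, 0.62, 0.54, 0.61, -0.33],
    [0.31, 0.21, 0.19, 0.47, 0.45, 0.33, 0.28, 0.43, 0.51, 0.43, 0.51, -0.29, 0.76],
]

ACSI_N = 774


def acsi_moments() -> MomentSet:
    """The 14-indicator ACSI moment set (printed to two decimals)."""
    J = 14
    S = np.diag(np.array(_ACSI_VARIANCES, dtype=float))
    for j, row in enumerate(_ACSI_UPPER):
        for off, v in enumerate(row):
            k = j + 1 + off
            S[j, k] = S[k, j] = v
    return MomentSet(_ACSI_NAMES, np.array(_ACSI_MEANS), S, ACSI_N)


def acsi_model(variant: str = "true") -> ModelSpec:
    """The six-component ACSI structural model.

    Components: customer expectations (CE: z1-z3), perceived quality
    (PQ: z4-z6), perceived value (PV: z7-z8), customer satisfaction
    (CS: z9-z11), customer complaints (CC: z12) — all convex — and customer
    loyalty (CL: z13, z14), standardized because its two indicators are on
    different scales.

    ``variant``:

    * ``"true"`` — the nine-path ACSI model;
    * ``"under"`` — drops the PV -> CS path;
    * ``"over"`` — adds a spurious CE -> CL path.
    """
    edges = [
        ("CE", "PQ"), ("CE", "PV"), ("PQ", "PV"),
        ("CE", "CS"), ("PQ", "CS"), ("PV", "CS"),
        ("CS", "CC"), ("CS", "CL"), ("CC", "CL"),
    ]
    if variant == "under":
        edges.remove(("PV", "CS"))
    elif variant == "over":
        edges.append(("CE", "CL"))
    elif variant != "true":
        raise ValueError(f"unknown ACSI variant {variant!r}")
    spec = ModelSpec(
        blocks={
            "CE": ["z1", "z2", "z3"],
            "PQ": ["z4", "z5", "z6"],
            "PV": ["z7", "z8"],
            "CS": ["z9", "z10", "z11"],
            "CC": ["z12"],
            "CL": ["z13", "z14"],
        },
        scale_type={"CL": STANDARDIZED},
        structural_edges=edges,
    )
    return validate_spec(spec)


def load_acsi_fixture(variant: str = "true") -> tuple[MomentSet, ModelSpec]:
    """The ACSI moment set together with the model specification."""
    return acsi_moments(), acsi_model(variant)
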