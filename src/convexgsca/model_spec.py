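"""Model specification for structured component models with convex and
standardized components.

A model is declared by three pieces of structure:

* **blocks** — each component is a weighted sum of an ordered, disjoint
  block of observed indicators (the weighted relation model, ``gamma = W'z``);
* **scale types** — a component is *convex* (weights sum to one, scores stay
  on the indicators' original scale) or *standardized* (unit variance,
  indicators standardized before fitting);
* **structural edges** — directed paths among components
  (``gamma = b0 + B'gamma + zeta``).

Validation derives the zero/free patterns of the weight matrix ``W``
(J x P), loading matrix ``C`` (P x J) and path matrix ``B`` (P x P), and the
dependency bookkeeping needed by the penalty matrix and the fit indexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ModelSpec",
    "DependencyMask",
    "ModelSpecError",
    "validate_spec",
    "read_spec",
    "write_spec",
    "spec_from_dict",
    "spec_to_dict",
]

CONVEX = "convex"
STANDARDIZED = "standardized"


class ModelSpecError(ValueError):
    """Raised when a model specification is structurally invalid."""


@dataclass(frozen=True)
class DependencyMask:
    """Which variables are dependent (have at least one incoming arrow).

    All indicators whose loadings are estimated are dependent in the
    measurement model; a component is dependent when it has at least one
    incoming structural path.  ``T = P + J`` is the total variable count and
    ``T_Y`` the number of dependent variables — both enter the reduction
    identities linking the unstandardized fit indexes to their classic
    standardized counterparts.
    """

    dependent_indicators: tuple[str, ...]
    dependent_components: tuple[str, ...]
    T: int
    T_Y: int


@dataclass
class ModelSpec:
    """Declaration of a component model.

    Parameters
    ----------
    blocks
        Mapping from component name to the ordered list of its indicators.
        Blocks must be non-empty and disjoint.
    scale_type
        Per component, ``"convex"`` or ``"standardized"``.  Missing entries
        default to convex.
    structural_edges
        Directed ``(predictor, outcome)`` pairs among component names.
    nonneg_weights
        If true, convex weights are additionally constrained non-negative
        during estimation (they always sum to one).
    """

    blocks: dict[str, list[str]]
    scale_type: dict[str, str] = field(default_factory=dict)
    structural_edges: list[tuple[str, str]] = field(default_factory=list)
    nonneg_weights: bool = False

    # -- derived on validation ------------------------------------------
    _validated: bool = field(default=False, repr=False)

    @property
    def component_names(self) -> list[str]:
        return list(self.blocks)

    @property
    def indicator_names(self) -> list[str]:
        return [z for block in self.blocks.values() for z in block]

    @property
    def P(self) -> int:
        return len(self.blocks)

    @property
    def J(self) -> int:
        return len(self.indicator_names)

    def block_indices(self, comp: str) -> np.ndarray:
        """Positions of a component's indicators in the global ordering."""
        names = self.indicator_names
        return np.array([names.index(z) for z in self.blocks[comp]], dtype=int)

    def component_index(self, comp: str) -> int:
        return self.component_names.index(comp)

    def scale_of(self, comp: str) -> str:
        return self.scale_type.get(comp, CONVEX)

    def is_weight_fixed(self, comp: str) -> bool:
        """Single-indicator convex blocks have weight identically one."""
        return self.scale_of(comp) == CONVEX and len(self.blocks[comp]) == 1

    # -- patterns -------------------------------------------------------
    def w_pattern(self) -> np.ndarray:
        """Boolean J x P mask: weight (j, p) is free iff indicator j is in
        block p (a fixed single-indicator weight is not counted as free)."""
        pat = np.zeros((self.J, self.P), dtype=bool)
        for p, comp in enumerate(self.component_names):
            if self.is_weight_fixed(comp):
                continue
            pat[self.block_indices(comp), p] = True
        return pat

    def block_membership(self) -> np.ndarray:
        """Boolean J x P mask of block membership (fixed weights included)."""
        pat = np.zeros((self.J, self.P), dtype=bool)
        for p, comp in enumerate(self.component_names):
            pat[self.block_indices(comp), p] = True
        return pat

    def c_pattern(self) -> np.ndarray:
        """Boolean P x J loading mask: (p, j) free iff j in block p."""
        return self.block_membership().T

    def b_pattern(self) -> np.ndarray:
        """Boolean P x P path mask: (q, p) free iff edge q -> p declared."""
        pat = np.zeros((self.P, self.P), dtype=bool)
        names = self.component_names
        for pred, out in self.structural_edges:
            pat[names.index(pred), names.index(out)] = True
        return pat

    def dependency_mask(self) -> DependencyMask:
        dep_z = tuple(self.indicator_names)  # all loadings estimated
        bpat = self.b_pattern()
        dep_g = tuple(
            c for p, c in enumerate(self.component_names) if bpat[:, p].any()
        )
        T = self.P + self.J
        return DependencyMask(dep_z, dep_g, T, len(dep_z) + len(dep_g))

    def has_cycle(self) -> bool:
        order = _topological_order(self.b_pattern())
        return order is None

    def topological_order(self) -> list[int] | None:
        """Component indices in a predecessor-first order, or None if cyclic."""
        return _topological_order(self.b_pattern())


def _topological_order(bpat: np.ndarray) -> list[int] | None:
    P = bpat.shape[0]
    indeg = bpat.sum(axis=0).astype(int)
    queue = [p for p in range(P) if indeg[p] == 0]
    order: list[int] = []
    indeg = indeg.copy()
    while queue:
        q = queue.pop()
        order.append(q)
        for p in np.flatnonzero(bpat[q]):
            indeg[p] -= 1
            if indeg[p] == 0:
                queue.append(int(p))
    return order if len(order) == P else None


def validate_spec(spec: ModelSpec) -> ModelSpec:
    """Check structural invariants and return the spec marked validated.

    Raises
    ------
    ModelSpecError
        On an empty block, an indicator assigned to two blocks, a duplicate
        component name, an unknown scale type, a structural edge referencing
        an unknown component, or a self-loop.
    Warns
    -----
    UserWarning
        When the structural graph is cyclic (the estimator handles cycles,
        but the model-implied covariance and hence GFI/SRMR are undefined).
    """
    if not spec.blocks:
        raise ModelSpecError("model must declare at least one component")
    seen: set[str] = set()
    for comp, block in spec.blocks.items():
        if not block:
            raise ModelSpecError(f"component {comp!r} has an empty block")
        for z in block:
            if z in seen:
                raise ModelSpecError(f"indicator {z!r} assigned to two blocks")
            seen.add(z)
    names = set(spec.component_names)
    for comp, sc in spec.scale_type.items():
        if comp not in names:
            raise ModelSpecError(f"scale declared for unknown component {comp!r}")
        if sc not in (CONVEX, STANDARDIZED):
            raise ModelSpecError(f"unknown scale type {sc!r} for {comp!r}")
    for pred, out in spec.structural_edges:
        if pred not in names or out not in names:
            raise ModelSpecError(f"structural edge {pred!r} -> {out!r} references an unknown component")
        if pred == out:
            raise ModelSpecError(f"self-loop on component {pred!r}")
    if len(set(map(tuple, spec.structural_edges))) != len(spec.structural_edges):
        raise ModelSpecError("duplicate structural edge")
    if spec.has_cycle():
        warnings.warn("structural graph is cyclic; implied-covariance fit indexes are unavailable", UserWarning, stacklevel=2)
    spec._validated = True
    return spec


# ---------------------------------------------------------------------------
# Structured text config (YAML) round trip
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "components": {
            comp: {
                "indicators": list(spec.blocks[comp]),
                "scale": spec.scale_of(comp),
            }
            for comp in spec.component_names
        },
        "edges": [f"{a} -> {b}" for a, b in spec.structural_edges],
        "nonneg_weights": bool(spec.nonneg_weights),
    }


def spec_from_dict(d: dict) -> ModelSpec:
    blocks: dict[str, list[str]] = {}
    scale: dict[str, str] = {}
    for comp, entry in d["components"].items():
        blocks[comp] = list(entry["indicators"])
        scale[comp] = entry.get("scale", CONVEX)
    edges = []
    for e in d.get("edges", []):
        a, b = (s.strip() for s in e.split("->"))
        edges.append((a, b))
    return validate_spec(
        ModelSpec(blocks, scale, edges, bool(d.get("nonneg_weights", False)))
    )


def write_spec(spec: ModelSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def read_spec(path: str) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
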