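import numpy as np
import pytest

from convexgsca.model_spec import ModelSpec, validate_spec
from convexgsca.moments_io import MomentSet, load_acsi_fixture


@pytest.fixture(scope="session")
def acsi():
    """(moments, spec) of the customer-satisfaction example."""
    return load_acsi_fixture()


def random_model(rng, allow_standardized=True, max_components=4, max_block=4):
    """A random valid spec plus positive-definite moments on its indicators.

    Structural edges form a random DAG over the declaration order, so every
    generated model is recursive.
    """
    P = int(rng.integers(2, max_components + 1))
    blocks, scale = {}, {}
    j = 0
    for p in range(P):
        k = int(rng.integers(2, max_block + 1))
        comp = f"g{p + 1}"
        blocks[comp] = [f"z{j + i + 1}" for i in range(k)]
        j += k
        if allow_standardized and rng.random() < 0.3:
            scale[comp] = "standardized"
    comps = list(blocks)
    edges = [
        (comps[a], comps[b])
        for a in range(P)
        for b in range(a + 1, P)
        if rng.random() < 0.5
    ]
    if not edges:  # keep at least one dependent component
        edges = [(comps[0], comps[-1])]
    spec = validate_spec(ModelSpec(blocks, scale, edges))

    J = spec.J
    A = rng.standard_normal((J, J + 2))
    S = A @ A.T / (J + 2) + 0.5 * np.eye(J)
    scl = rng.uniform(0.5, 3.0, J)
    S = S * np.outer(scl, scl)
    mu = rng.uniform(-2.0, 8.0, J)
    moments = MomentSet(tuple(spec.indicator_names), mu, S, 200)
    return spec, moments
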