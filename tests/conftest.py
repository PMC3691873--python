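import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from addbn import (ABNSpec, DAG, Dataset, Family, NodeModel, VariableSpec,
                   simulate)


def random_mixed_dataset(seed, V=4, n=120):
    """Random dataset with genuine cross-dependencies, alternating families."""
    rng = np.random.default_rng(seed)
    cols, specs = {}, []
    prev = None
    for i in range(V):
        name = f"v{i}"
        if i % 2 == 0:
            x = rng.normal(size=n)
            if prev is not None:
                x = x + rng.uniform(-0.8, 0.8) * cols[prev]
            cols[name] = x
            specs.append(VariableSpec(name, Family.GAUSSIAN))
        else:
            eta = rng.uniform(-0.8, 0.8) * cols[prev]
            b = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            if len(set(b)) < 2:
                b[0] = 1 - b[0]
            cols[name] = b
            specs.append(VariableSpec(name, Family.BERNOULLI))
        prev = name
    return Dataset(pd.DataFrame(cols), specs)


def random_constraints(seed, names):
    """Random but self-consistent ban/retain constraint sets."""
    from addbn import SearchConstraints
    rng = np.random.default_rng(seed)
    banned, retained = set(), set()
    pairs = [(p, c) for p in names for c in names if p != c]
    for pair in pairs:
        u = rng.random()
        if u < 0.1:
            banned.add(pair)
        elif u < 0.15 and (pair[1], pair[0]) not in retained:
            retained.add(pair)
    retained -= banned
    retained -= {(c, p) for p, c in retained}
    try:
        cons = SearchConstraints(banned_arcs=frozenset(banned),
                                 retained_arcs=frozenset(retained))
        cons.validate_against(tuple(names))
        return cons
    except Exception:
        return SearchConstraints(banned_arcs=frozenset(banned))


@pytest.fixture
def tiny_mixed_dataset():
    """Small deterministic mixed dataset for plumbing tests."""
    rng = np.random.default_rng(7)
    g1 = rng.normal(size=60)
    g2 = 0.8 * g1 + rng.normal(size=60)
    b1 = rng.binomial(1, 1 / (1 + np.exp(-g1)), 60).astype(float)
    frame = pd.DataFrame({"b1": b1, "g1": g1, "g2": g2})
    specs = [VariableSpec("b1", Family.BERNOULLI),
             VariableSpec("g1", Family.GAUSSIAN),
             VariableSpec("g2", Family.GAUSSIAN)]
    return Dataset(frame, specs)


@pytest.fixture(scope="session")
def six_node_spec():
    """Fixed 6-node mixed additive BN: the end-to-end recovery benchmark."""
    import addbn
    return addbn.six_node_benchmark_spec()


@pytest.fixture(scope="session")
def five_node_strong_spec():
    """5-node network with uniformly strong effects (standardized >= 1)."""
    import addbn
    return addbn.five_node_strong_spec()


@pytest.fixture
def six_node_data(six_node_spec):
    return simulate(six_node_spec, 500, 11)
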