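"""Shared fixtures: small hand-built trees and session-scoped pools of
simulated trees reused across test modules (all generated at test time)."""

from __future__ import annotations

import numpy as np
import pytest

from extsig import treesim as ts
from extsig.timetree import drop_extinct, read_newick


@pytest.fixture()
def rng():
    return np.random.default_rng(20160322)


@pytest.fixture()
def three_tip_tree():
    """((A:1,B:1):1,C:2); ultrametric, crown age 2."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def tree_with_extinct():
    """3-tip tree in which X went extinct at age 0.5."""
    return read_newick("((A:1,B:1):1,X:1.5);")


@pytest.fixture(scope="session")
def bd_complete_pool():
    """120 complete BD trees (lambda=2, mu=1) conditioned on 20 extant tips."""
    rng = np.random.default_rng(101)
    return ts.simulate_trees(ts.BDRegime(lam=2.0, mu=1.0), 120, rng)


@pytest.fixture(scope="session")
def bd_reconstructed_pool(bd_complete_pool):
    return [drop_extinct(t) for t in bd_complete_pool]


@pytest.fixture(scope="session")
def me_reconstructed_pool():
    """12 reconstructed trees under the mass-extinction regime
    (lambda=2, mu=0.3 -> event at age 1, survival 0.1 -> lambda=2, mu=1)."""
    rng = np.random.default_rng(202)
    sim = ts.ConditionedSimulator(ts.me_regime(), ts.SimConfig(n_extant=20))
    return [drop_extinct(sim.sample(rng)) for _ in range(12)]


@pytest.fixture(scope="session")
def yule_tree_pool():
    """400 pure-birth trees with 20 extant tips (identical complete and
    reconstructed by construction)."""
    rng = np.random.default_rng(303)
    return ts.simulate_trees(ts.BDRegime(lam=1.0, mu=0.0), 400, rng)
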