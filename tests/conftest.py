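"""Shared fixtures and independent oracles.

The brute-force mating-table oracle enumerates every (mother genotype,
transmitted maternal allele, paternal allele) triple directly from the model's
verbal description, independently of the vectorized recursion it checks.  The
heavy Monte-Carlo fixtures are session-scoped so the acceptance tests and the
qualitative checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import matsel as ms


def mating_table_oracle(state: ms.PopulationState, fitness: ms.FitnessSet):
    """One generation by exhaustive enumeration of the mating table."""
    n = state.n
    p = state.allele_frequencies()
    y = np.zeros((n, n))
    for k in range(n):
        for l in range(k, n):
            mother_freq = state.x[k, l]
            transmissions = [(k, 1.0)] if k == l else [(k, 0.5), (l, 0.5)]
            for m_allele, m_prob in transmissions:
                for a in range(n):  # paternal allele
                    i, j = min(m_allele, a), max(m_allele, a)
                    w = fitness[((i, j), (k, l))]
                    y[i, j] += mother_freq * m_prob * p[a] * w
    wbar = y.sum()
    x = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            x[i, j] = x[j, i] = y[i, j] / wbar
    return ms.PopulationState(x), wbar


def constant_viability_recursion(p: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Classical one-locus viability selection on allele frequencies.

    p'_i = p_i (V p)_i / (p^T V p), the standard recursion the maternal model
    must reduce to when fitness is independent of the mother.
    """
    marginal = v @ p
    return p * marginal / (p @ marginal)


def random_state(n: int, g: np.random.Generator) -> ms.PopulationState:
    """A random valid genotype-frequency state (not necessarily HW)."""
    raw = g.dirichlet(np.ones(n * (n + 1) // 2))
    x = np.zeros((n, n))
    t = 0
    for i in range(n):
        for j in range(i, n):
            x[i, j] = x[j, i] = raw[t]
            t += 1
    return ms.PopulationState(x)


@pytest.fixture(scope="session")
def paramspace_n2():
    """Table-1-scale n=2 experiment: 1e4 fitness sets x 20 starts."""
    return ms.estimate_potential(2, 10_000, 20, ms.RngConfig(12345).child(2))


@pytest.fixture(scope="session")
def paramspace_n3():
    """Table-1-scale n=3 experiment: 1e4 fitness sets x 20 starts."""
    return ms.estimate_potential(3, 10_000, 20, ms.RngConfig(12345).child(3))


@pytest.fixture(scope="session")
def paramspace_n4():
    """Table-1-scale n=4 experiment: 2e4 fitness sets x 20 starts."""
    return ms.estimate_potential(4, 20_000, 20, ms.RngConfig(12345).child(4))


@pytest.fixture(scope="session")
def construction_200():
    """200 constructionist replicates of 1e4 generations each."""
    cfg = ms.ConstructionConfig(generations=10_000, replicates=200, rng=ms.RngConfig(12345))
    return [ms.run_construction(cfg, replicate=r) for r in range(200)]
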