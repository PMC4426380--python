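"""Seeded generation of random fitness sets and random initial conditions.

All randomness in the package flows through :class:`RngConfig`, a thin handle
over numpy's PCG64 seeded via SeedSequence.  A replicate (or fitness set) r of
any experiment derives its stream as ``root.child(r)``, so results are a pure
function of (seed, r) and independent of how many other replicates ran.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FitnessSet, PopulationState, count_parameters, hardy_weinberg_total

__all__ = [
    "RngConfig",
    "random_fitness_set",
    "broken_stick_frequencies",
    "hardy_weinberg_state",
]

GENERATOR_NAME = "numpy PCG64 (SeedSequence spawn streams)"


@dataclass(frozen=True)
class RngConfig:
    """Reproducible random-stream handle: (seed, stream key)."""

    seed: int
    stream: tuple = ()

    def child(self, k: int) -> "RngConfig":
        return RngConfig(self.seed, self.stream + (int(k),))

    def generator(self) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=int(self.seed), spawn_key=self.stream)
        return np.random.Generator(np.random.PCG64(ss))


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, RngConfig):
        return rng.generator()
    raise TypeError(f"expected RngConfig or numpy Generator, got {type(rng)!r}")


def random_fitness_set(n: int, rng) -> FitnessSet:
    """One independent U[0,1] draw per canonical pair, in stable enumeration order."""
    g = _as_generator(rng)
    return FitnessSet(n, g.uniform(size=count_parameters(n)))


def broken_stick_frequencies(n: int, rng) -> np.ndarray:
    """A frequency vector uniform on the simplex (broken-stick / MacArthur).

    The unit interval is broken at n-1 independent U[0,1] points; the spacings,
    in left-to-right (unranked) order, are the n frequencies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    g = _as_generator(rng)
    cuts = np.sort(g.uniform(size=n - 1))
    return np.diff(np.concatenate(([0.0], cuts, [1.0])))


def broken_stick_batch(n: int, size: int, rng) -> np.ndarray:
    """``size`` broken-stick vectors at once (rows sum to 1)."""
    g = _as_generator(rng)
    cuts = np.sort(g.uniform(size=(size, n - 1)), axis=1)
    edges = np.concatenate(
        (np.zeros((size, 1)), cuts, np.ones((size, 1))), axis=1
    )
    return np.diff(edges, axis=1)


def hardy_weinberg_state(p) -> PopulationState:
    """Expand allele frequencies to HW genotype proportions x_ii = p_i^2, x_ij = 2 p_i p_j."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p must be a non-empty 1-D frequency vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must be a probability vector summing to 1")
    return PopulationState(hardy_weinberg_total(p))
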